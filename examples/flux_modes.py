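"""Elementary flux modes and conservation relations of a small network.

Elementary flux modes are the minimal indivisible pathways through a
network: non-negative (on irreversible reactions) flux vectors v with
N·v = 0 and minimal support.  Computed exactly over rationals.
"""

from kinemet import (
    build_fixture,
    conservation_relations,
    elementary_flux_modes,
    stoichiometric_matrix,
)
from kinemet.core import Compartment, Model, RateLaw, Reaction, Species


def conv(rid, a, b):
    return Reaction(rid, reactants=((a, 1),), products=((b, 1),),
                    rate_law=RateLaw("mass_action", substrate_ids=(a,)))


# a diamond: two alternative routes from source to sink
diamond = Model(
    id="diamond",
    compartments=[Compartment("c")],
    species=[Species(s, compartment="c", boundary=s.startswith("Ext"))
             for s in ("ExtIn", "A", "B", "C", "D", "ExtOut")],
    reactions=[conv("in", "ExtIn", "A"), conv("ab", "A", "B"),
               conv("ac", "A", "C"), conv("bd", "B", "D"),
               conv("cd", "C", "D"), conv("out", "D", "ExtOut")],
)

N = stoichiometric_matrix(diamond)
for i, mode in enumerate(elementary_flux_modes(N)):
    print(f"mode {i}: " + ", ".join(f"{r}={w}" for r, w in mode.as_dict().items() if w))
print("Two modes = the two alternative routes (via B and via C).\n")

phos = build_fixture("phosphagen")
Np = stoichiometric_matrix(phos)
print("phosphagen conservation relations (weighted species totals constant):")
for rel in conservation_relations(Np):
    terms = " + ".join(f"{w}*{s}" if w != 1 else s for s, w in rel.items() if w)
    print(f"  {terms} = const")
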