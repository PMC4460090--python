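import pytest

from kinemet.core import Compartment, Model, RateLaw, Reaction, Species


def simple_model(reactions, species_defs, model_id="m"):
    """Helper: model with one default compartment."""
    species = [
        Species(sid, compartment="c", initial_concentration=conc, boundary=boundary)
        for sid, conc, boundary in species_defs
    ]
    return Model(
        id=model_id,
        compartments=[Compartment("c", "cytosol", "default")],
        species=species,
        reactions=reactions,
    )


@pytest.fixture
def ab_closed():
    """Closed A ↔ B with equal forward/backward kinetics (V=1, first order)."""
    return simple_model(
        reactions=[
            Reaction("f", reactants=(("A", 1),), products=(("B", 1),),
                     rate_law=RateLaw("mass_action", V=1.0, substrate_ids=("A",))),
            Reaction("b", reactants=(("B", 1),), products=(("A", 1),),
                     rate_law=RateLaw("mass_action", V=1.0, substrate_ids=("B",))),
        ],
        species_defs=[("A", 3.0, False), ("B", 1.0, False)],
        model_id="ab_closed",
    )


@pytest.fixture
def fed_chain():
    """Boundary-fed chain source → A → sink with saturation laws."""
    return simple_model(
        reactions=[
            Reaction("in", reactants=(("Src", 1),), products=(("A", 1),),
                     rate_law=RateLaw("saturation", V=1.0, Km=2.0,
                                      substrate_ids=("Src",))),
            Reaction("out", reactants=(("A", 1),), products=(("Snk", 1),),
                     rate_law=RateLaw("saturation", V=1.0, Km=0.7,
                                      substrate_ids=("A",))),
        ],
        species_defs=[("Src", 4.0, True), ("A", 0.1, False), ("Snk", 0.0, True)],
        model_id="fed_chain",
    )
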