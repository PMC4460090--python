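"""Declarative representation of a compartmentalized kinetic metabolic network.

A :class:`Model` is a set of compartments, species and reactions.  Each
reaction carries a :class:`RateLaw` of one of three kinds that cover the
kinetics used throughout the energy-pool network:

``saturation``
    Michaelis–Menten form ``V·x/(Km+x)`` in a single substrate ``x``.
``mass_action``
    ``V·x1·x2·…`` — the product of one or more substrate concentrations.
``constant``
    ``V`` — a fixed flux (e.g. a clamped boundary inflow).

Concentrations are in μM and time in seconds throughout the package; ``V``
defaults to 1 (the network's default maximal-rate scale) and compartment
volumes default to 1, so rates are already amount-based and no extra volume
scaling is applied.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import sympy

__all__ = [
    "Compartment",
    "Species",
    "RateLaw",
    "Reaction",
    "Model",
    "StoichiometricMatrix",
    "ModelError",
    "stoichiometric_matrix",
    "conservation_relations",
    "validate_model",
]

COMPARTMENT_KINDS = {
    "mitochondrion",
    "inner_membrane",
    "intermembrane_space",
    "outer_membrane",
    "default",
}

SPECIES_ROLES = {
    "substrate",
    "metabolite",
    "enzyme",
    "carrier",
    "cofactor",
    "energy_currency",
}

RATE_LAW_KINDS = {"saturation", "mass_action", "constant"}


class ModelError(ValueError):
    """Structural error in a model definition (unknown species, bad rate law…)."""


@dataclass
class Compartment:
    id: str
    name: str = ""
    kind: str = "default"
    volume: float = 1.0


@dataclass
class Species:
    """A chemical species.

    ``boundary=True`` clamps the concentration: the species participates in
    rate laws but its own time derivative is pinned to zero.
    """

    id: str
    name: str = ""
    compartment: str = "default"
    initial_concentration: float = 0.0
    role: str = "metabolite"
    boundary: bool = False


@dataclass
class RateLaw:
    """Tagged kinetic form with rate scale ``V`` and (for saturation) ``Km``."""

    kind: str
    V: float = 1.0
    Km: float | None = None
    substrate_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        # mass action is commutative; keep the factor list canonical so
        # serialization round trips compare equal
        if self.kind == "mass_action":
            self.substrate_ids = tuple(sorted(self.substrate_ids))
        else:
            self.substrate_ids = tuple(self.substrate_ids)

    def rate(self, conc: Mapping[str, float]) -> float:
        """Evaluate the law at a concentration map (μM) → rate (μM/s)."""
        if self.kind == "constant":
            return self.V
        if self.kind == "saturation":
            (sid,) = self.substrate_ids
            x = conc[sid]
            return self.V * x / (self.Km + x)
        if self.kind == "mass_action":
            r = self.V
            for sid in self.substrate_ids:
                r *= conc[sid]
            return r
        raise ModelError(f"unknown rate-law kind {self.kind!r}")


@dataclass
class Reaction:
    """reactants/products: (species id, positive integer stoichiometry) pairs.

    Modifiers (enzymes, carriers) influence no stoichiometric column entry;
    enzyme inhibition is modelled by scaling ``rate_law.V``.
    """

    id: str
    reactants: tuple[tuple[str, int], ...] = ()
    products: tuple[tuple[str, int], ...] = ()
    modifiers: tuple[str, ...] = ()
    rate_law: RateLaw = field(default_factory=lambda: RateLaw("constant"))
    reversible: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        self.reactants = tuple((s, int(n)) for s, n in self.reactants)
        self.products = tuple((s, int(n)) for s, n in self.products)
        self.modifiers = tuple(self.modifiers)

    def net_stoichiometry(self, species_id: str) -> int:
        n = 0
        for s, k in self.products:
            if s == species_id:
                n += k
        for s, k in self.reactants:
            if s == species_id:
                n -= k
        return n


@dataclass
class Model:
    id: str = "model"
    name: str = ""
    compartments: list[Compartment] = field(default_factory=list)
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    notes: str = ""

    # -- lookups -----------------------------------------------------------
    def species_by_id(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def reaction_by_id(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def dynamic_species_ids(self) -> list[str]:
        return [s.id for s in self.species if not s.boundary]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def initial_state(self, overrides: Mapping[str, float] | None = None) -> dict[str, float]:
        state = {s.id: float(s.initial_concentration) for s in self.species}
        if overrides:
            for sid, v in overrides.items():
                if sid not in state:
                    raise ModelError(f"override references unknown species {sid!r}")
                state[sid] = float(v)
        return state

    def copy(self) -> "Model":
        return copy.deepcopy(self)


@dataclass
class StoichiometricMatrix:
    """Species × reactions matrix N of net stoichiometric coefficients.

    Rows are non-boundary species; products enter positive, reactants
    negative.  Steady state means N·v = 0.
    """

    species_ids: list[str]
    reaction_ids: list[str]
    matrix: np.ndarray  # integer, shape (n_species, n_reactions)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def row(self, species_id: str) -> np.ndarray:
        return self.matrix[self.species_ids.index(species_id)]

    def column(self, reaction_id: str) -> np.ndarray:
        return self.matrix[:, self.reaction_ids.index(reaction_id)]


def stoichiometric_matrix(model: Model) -> StoichiometricMatrix:
    """Build N over the model's non-boundary species.

    Raises :class:`ModelError` naming the offending reaction if a reaction
    references an unknown species.
    """
    known = set(model.species_ids)
    for rxn in model.reactions:
        for sid, _ in (*rxn.reactants, *rxn.products):
            if sid not in known:
                raise ModelError(
                    f"reaction {rxn.id!r} references unknown species {sid!r}"
                )
    rows = model.dynamic_species_ids
    index = {sid: i for i, sid in enumerate(rows)}
    cols = model.reaction_ids
    N = np.zeros((len(rows), len(cols)), dtype=int)
    for j, rxn in enumerate(model.reactions):
        for sid, n in rxn.reactants:
            if sid in index:
                N[index[sid], j] -= n
        for sid, n in rxn.products:
            if sid in index:
                N[index[sid], j] += n
    return StoichiometricMatrix(rows, cols, N)


def conservation_relations(matrix: StoichiometricMatrix) -> list[dict[str, int]]:
    """Integer-weight left-null-space vectors of N (moiety conservation).

    Each returned mapping g (species id → integer weight) satisfies
    gᵀ·N = 0 exactly; the vectors are linearly independent and there are
    ``#rows − rank(N)`` of them.  Computed over rationals via sympy and
    scaled to coprime integers.
    """
    N = sympy.Matrix(matrix.matrix.tolist())
    out: list[dict[str, int]] = []
    for vec in N.T.nullspace():
        denoms = [Fraction(sympy.Rational(x)).denominator for x in vec]
        lcm = int(np.lcm.reduce(denoms)) if denoms else 1
        ints = [int(sympy.Rational(x) * lcm) for x in vec]
        g = int(np.gcd.reduce([abs(v) for v in ints if v != 0] or [1]))
        ints = [v // g for v in ints]
        # canonical sign: first nonzero entry positive
        first = next((v for v in ints if v != 0), 1)
        if first < 0:
            ints = [-v for v in ints]
        out.append(dict(zip(matrix.species_ids, ints)))
    return out


def _rate_law_violations(rxn: Reaction) -> list[str]:
    law = rxn.rate_law
    bad: list[str] = []
    if law.kind not in RATE_LAW_KINDS:
        bad.append(f"reaction {rxn.id}: unknown rate-law kind {law.kind!r}")
        return bad
    if law.V is None or law.V <= 0:
        bad.append(f"reaction {rxn.id}: rate-law V must be positive")
    if law.kind == "saturation":
        if law.Km is None or law.Km <= 0:
            bad.append(f"reaction {rxn.id}: saturation law requires Km > 0")
        if len(law.substrate_ids) != 1:
            bad.append(
                f"reaction {rxn.id}: saturation law requires exactly one substrate"
            )
    if law.kind == "mass_action" and not law.substrate_ids:
        bad.append(f"reaction {rxn.id}: mass-action law requires >= 1 substrate")
    return bad


def validate_model(model: Model) -> list[str]:
    """Check all model invariants; return a list of violation messages.

    Empty list ⇔ the model is well-formed.  Never raises; idempotent and
    side-effect free.
    """
    report: list[str] = []
    comp_ids = [c.id for c in model.compartments]
    if len(set(comp_ids)) != len(comp_ids):
        report.append("duplicate compartment ids")
    for c in model.compartments:
        if c.volume <= 0:
            report.append(f"compartment {c.id}: volume must be > 0")
    sp_ids = model.species_ids
    if len(set(sp_ids)) != len(sp_ids):
        report.append("duplicate species ids")
    known_comp = set(comp_ids)
    for s in model.species:
        if s.initial_concentration < 0:
            report.append(f"species {s.id}: negative initial concentration")
        if known_comp and s.compartment not in known_comp:
            report.append(f"species {s.id}: unknown compartment {s.compartment!r}")
    known_sp = set(sp_ids)
    rxn_ids = model.reaction_ids
    if len(set(rxn_ids)) != len(rxn_ids):
        report.append("duplicate reaction ids")
    seen_signatures: dict[tuple, str] = {}
    for rxn in model.reactions:
        if not rxn.reactants and not rxn.products:
            report.append(f"reaction {rxn.id}: no reactants or products")
        for sid, n in (*rxn.reactants, *rxn.products):
            if sid not in known_sp:
                report.append(f"reaction {rxn.id}: unknown species {sid!r}")
            if n <= 0:
                report.append(f"reaction {rxn.id}: non-positive stoichiometry for {sid}")
        for sid in rxn.modifiers:
            if sid not in known_sp:
                report.append(f"reaction {rxn.id}: unknown modifier {sid!r}")
            if any(sid == s for s, _ in (*rxn.reactants, *rxn.products)):
                report.append(
                    f"reaction {rxn.id}: modifier {sid} also appears in stoichiometry"
                )
        for sid in rxn.rate_law.substrate_ids:
            if sid not in known_sp:
                report.append(
                    f"reaction {rxn.id}: rate law references unknown species {sid!r}"
                )
        report.extend(_rate_law_violations(rxn))
        # redundancy rule: same reactant set, product set and rate-law kind
        sig = (
            frozenset(rxn.reactants),
            frozenset(rxn.products),
            rxn.rate_law.kind,
        )
        if sig in seen_signatures:
            report.append(
                f"reaction {rxn.id}: redundant with {seen_signatures[sig]} "
                "(same reactants, products and rate-law kind)"
            )
        else:
            seen_signatures[sig] = rxn.id
    return report
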