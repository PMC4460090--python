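"""Programmatic builders for the energy-pool subnetworks used throughout the
package, plus seeded random models for oracle comparisons.

The full curated 173-reaction network is not redistributable, so these
fixtures realize the printed subnetworks: the glucose production/consumption
block, the ATP neighbourhood around glycolysis, the creatine-phosphate
(phosphagen) buffer, a lumped TCA segment around alpha-ketoglutarate
dehydrogenase (AKGDHC), and a C22 beta-oxidation chain with the carnitine
shuttle.  Michaelis constants come from the printed rate equations; initial
concentrations that were never printed (enzymes, intermediates) are
fixture-chosen nominal values in the 1e-2 – 1e2 μM range and are documented
next to each builder.  Directional claims in the test suite are chosen to be
independent of those nominal values.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from .core import Compartment, Model, RateLaw, Reaction, Species

__all__ = ["KM", "CONSTANTS", "FIXTURE_NAMES", "build_fixture", "random_network"]


# Michaelis constants (μM) exactly as printed in the glucose and ATP rate
# equations; keys name the saturating substrate.
KM: Mapping[str, float] = MappingProxyType({
    "limit_dextrin": 0.08,
    "sucrose": 10.0,
    "trehalose": 1.37,
    "glucose": 0.048,
    "g6p": 2.0,
    "unbranched_polymer": 1.0,
    "fructose": 0.58,
    "glyceraldehyde": 0.31,
    "galactose": 970.0,
    "pep": 5.8,
    "bpga13": 300.0,
    "pyruvate": 0.11,
    "acetyl_coa": 40.0,
    "obesity_K": 1.0,
})


@dataclass(frozen=True)
class FixtureConstants:
    """Printed constants used as inputs, with provenance.

    ``atp_alpha``/``atp_beta`` are the coefficients of the reduced ATP ODE
    dY/dx = alpha·x + beta as printed; the frozen concentrations behind them
    were never published, so they are stored as printed-underived inputs and
    never recomputed.  The starvation/exercise betas are the constant terms
    of the respective printed reduced ODEs.
    """

    hypoglycaemic_glucose: float = 400.0       # μM
    hyperglycaemic_glucose: float = 11100.0    # μM ("more than"; fixed for reproducibility)
    atp_alpha: float = -57.4                   # printed, underived
    atp_beta: float = -3.207                   # printed, underived
    starvation_beta: float = -1.1586           # constant of the starvation reduced ODE
    exercise_beta: float = -0.9976             # constant of the exercise reduced ODE
    km: Mapping[str, float] = field(default_factory=lambda: KM)


CONSTANTS = FixtureConstants()

FIXTURE_NAMES = (
    "glucose_block",
    "core_energy",
    "phosphagen",
    "tca_dldd",
    "beta_oxidation",
)


def _mito_compartments() -> list[Compartment]:
    return [
        Compartment("cyt", "cytosol", "default"),
        Compartment("mit", "mitochondrion", "mitochondrion"),
        Compartment("imm", "inner mitochondrial membrane", "inner_membrane"),
        Compartment("ims", "intermembrane space", "intermembrane_space"),
        Compartment("omm", "outer mitochondrial membrane", "outer_membrane"),
    ]


def _glucose_reactions() -> list[Reaction]:
    """The seven reactions of glucose: five producers, the RE85 NADH-coupled
    producer, and the single RE25 consumer (hexokinase, saturating at
    Km 0.048 μM)."""
    sat = lambda sid, km, V=1.0: RateLaw("saturation", V=V, Km=km, substrate_ids=(sid,))
    return [
        Reaction("RE32", reactants=(("LimitDextrin", 1),), products=(("Glucose", 1),),
                 rate_law=sat("LimitDextrin", KM["limit_dextrin"]), name="limit dextrinase"),
        Reaction("RE56", reactants=(("Sucrose", 1),), products=(("Glucose", 1),),
                 rate_law=sat("Sucrose", KM["sucrose"]), name="sucrase"),
        Reaction("RE80", reactants=(("Trehalose", 1),), products=(("Glucose", 1),),
                 rate_law=sat("Trehalose", KM["trehalose"]), name="trehalase"),
        Reaction("RE87", reactants=(("Lactose", 1),), products=(("Glucose", 1),),
                 rate_law=RateLaw("mass_action", V=1.0, substrate_ids=("Lactose",)),
                 name="lactase (first-order)"),
        Reaction("RE85", reactants=(("Lactose", 1), ("NADH", 1)),
                 products=(("Glucose", 1), ("NAD", 1)),
                 rate_law=RateLaw("mass_action", V=1.0, substrate_ids=("Lactose", "NADH")),
                 name="NADH-coupled lactose reduction"),
        Reaction("RE25", reactants=(("Glucose", 1), ("ATP", 1)),
                 products=(("G6P", 1), ("ADP", 1)),
                 rate_law=sat("Glucose", KM["glucose"]), name="hexokinase"),
        Reaction("RE26", reactants=(("G6P", 1),), products=(("Glucose", 1),),
                 rate_law=sat("G6P", KM["g6p"]), name="glucose-6-phosphatase"),
    ]


def _glucose_boundary_species() -> list[Species]:
    """Boundary pool around glucose; concentrations are fixture-chosen
    nominal values (μM) picked so the glucose consumer (V=1) can balance the
    summed inflows and a steady state exists."""
    b = lambda sid, c, role="substrate": Species(sid, compartment="cyt",
                                                 initial_concentration=c, role=role,
                                                 boundary=True)
    return [
        b("LimitDextrin", 0.02),
        b("Sucrose", 1.0),
        b("Trehalose", 0.3),
        b("Lactose", 0.05),
        b("NADH", 1.0, "energy_currency"),
        b("NAD", 1.0, "energy_currency"),
        b("G6P", 0.1, "metabolite"),
    ]


def _build_glucose_block() -> Model:
    species = [
        Species("Glucose", compartment="cyt", initial_concentration=400.0,
                role="substrate"),
        *_glucose_boundary_species(),
        Species("ATP", compartment="cyt", initial_concentration=2.0,
                role="energy_currency", boundary=True),
        Species("ADP", compartment="cyt", initial_concentration=2.0,
                role="energy_currency", boundary=True),
    ]
    return Model(
        id="glucose_block",
        name="glucose production/consumption block",
        compartments=_mito_compartments(),
        species=species,
        reactions=_glucose_reactions(),
        notes="Seven-reaction glucose neighbourhood; only glucose is dynamic.",
    )


def _build_core_energy() -> Model:
    """Glucose block + the ATP neighbourhood: ATP is a reactant in exactly
    RE25, RE27, RE34, RE36, RE79, RE84, RE88 and a product in RE28 and RE31.

    The unbranched-α1,4-polymer (glycogenolysis) step is carried as RE2
    without ATP stoichiometry.  Dynamic species: Glucose, ATP, ADP.
    """
    sat = lambda sid, km, V=1.0: RateLaw("saturation", V=V, Km=km, substrate_ids=(sid,))
    ma = lambda *sids: RateLaw("mass_action", V=1.0, substrate_ids=sids)
    b = lambda sid, c, role="metabolite": Species(sid, compartment="cyt",
                                                  initial_concentration=c, role=role,
                                                  boundary=True)
    species = [
        Species("Glucose", compartment="cyt", initial_concentration=400.0,
                role="substrate"),
        Species("ATP", compartment="cyt", initial_concentration=2.0,
                role="energy_currency"),
        Species("ADP", compartment="cyt", initial_concentration=2.0,
                role="energy_currency"),
        *_glucose_boundary_species(),
        # fixture-chosen boundary concentrations (μM): producers saturate to
        # flux 0.5 each; consumers sit at ~0.09 so total ATP drain < supply
        b("UnbranchedPolymer", 0.5, "substrate"),
        b("F6P", 0.005),
        b("PGA3", 0.005),
        b("Fructose", 0.058, "substrate"),
        b("Glyceraldehyde", 0.031, "substrate"),
        b("Galactose", 97.0, "substrate"),
        b("PEP", 5.8),
        b("BPGA13", 300.0),
        b("Pyruvate", 0.011),
        b("F16BP", 1.0),
        b("OAA", 1.0),
        b("F1P", 1.0),
        b("G3P", 1.0),
        b("Gal1P", 1.0),
    ]
    reactions = [
        *_glucose_reactions(),
        Reaction("RE2", reactants=(("UnbranchedPolymer", 1),), products=(("G6P", 1),),
                 rate_law=sat("UnbranchedPolymer", KM["unbranched_polymer"]),
                 name="glycogen phosphorylase (lumped)"),
        Reaction("RE27", reactants=(("F6P", 1), ("ATP", 1)),
                 products=(("F16BP", 1), ("ADP", 1)),
                 rate_law=ma("F6P", "ATP"), name="phosphofructokinase"),
        Reaction("RE34", reactants=(("Pyruvate", 1), ("ATP", 1)),
                 products=(("OAA", 1), ("ADP", 1)),
                 rate_law=sat("Pyruvate", KM["pyruvate"]), name="pyruvate carboxylase"),
        Reaction("RE36", reactants=(("PGA3", 1), ("ATP", 1)),
                 products=(("BPGA13", 1), ("ADP", 1)),
                 rate_law=ma("PGA3", "ATP"), name="phosphoglycerate kinase (reverse)"),
        Reaction("RE79", reactants=(("Fructose", 1), ("ATP", 1)),
                 products=(("F1P", 1), ("ADP", 1)),
                 rate_law=sat("Fructose", KM["fructose"]), name="fructokinase"),
        Reaction("RE84", reactants=(("Glyceraldehyde", 1), ("ATP", 1)),
                 products=(("G3P", 1), ("ADP", 1)),
                 rate_law=sat("Glyceraldehyde", KM["glyceraldehyde"]),
                 name="glyceraldehyde kinase"),
        Reaction("RE88", reactants=(("Galactose", 1), ("ATP", 1)),
                 products=(("Gal1P", 1), ("ADP", 1)),
                 rate_law=sat("Galactose", KM["galactose"]), name="galactokinase"),
        Reaction("RE28", reactants=(("BPGA13", 1), ("ADP", 1)),
                 products=(("PGA3", 1), ("ATP", 1)),
                 rate_law=sat("BPGA13", KM["bpga13"]), name="phosphoglycerate kinase"),
        Reaction("RE31", reactants=(("PEP", 1), ("ADP", 1)),
                 products=(("Pyruvate", 1), ("ATP", 1)),
                 rate_law=sat("PEP", KM["pep"]), name="pyruvate kinase"),
    ]
    return Model(
        id="core_energy",
        name="ATP/glucose core energy neighbourhood",
        compartments=_mito_compartments(),
        species=species,
        reactions=reactions,
        notes="Glucose block plus the 7-consuming/2-producing ATP reactions.",
    )


def _build_phosphagen() -> Model:
    """Closed creatine-phosphate buffer (creatine kinase, reaction RE182).

    The reversible kinase is split into forward (CrP + ADP → Cr + ATP) and
    backward columns; all four species are dynamic, so the ATP/ADP and
    Cr/CrP moieties are conserved exactly.
    """
    ma = lambda *sids: RateLaw("mass_action", V=1.0, substrate_ids=sids)
    species = [
        Species("ATP", compartment="cyt", initial_concentration=10.0,
                role="energy_currency"),
        Species("ADP", compartment="cyt", initial_concentration=5.0,
                role="energy_currency"),
        Species("Creatine", compartment="cyt", initial_concentration=5.0,
                role="metabolite"),
        Species("CreatinePhosphate", compartment="cyt", initial_concentration=25.0,
                role="metabolite"),
    ]
    reactions = [
        Reaction("RE182", reactants=(("CreatinePhosphate", 1), ("ADP", 1)),
                 products=(("Creatine", 1), ("ATP", 1)),
                 rate_law=ma("CreatinePhosphate", "ADP"),
                 name="creatine kinase (forward)"),
        Reaction("RE182r", reactants=(("ATP", 1), ("Creatine", 1)),
                 products=(("CreatinePhosphate", 1), ("ADP", 1)),
                 rate_law=ma("ATP", "Creatine"),
                 name="creatine kinase (backward)"),
    ]
    return Model(
        id="phosphagen",
        name="creatine-phosphate ATP buffer",
        compartments=[Compartment("cyt", "cytosol", "default")],
        species=species,
        reactions=reactions,
        notes="Closed phosphagen system; ATP+ADP and Cr+CrP are conserved moieties.",
    )


def _build_tca_dldd() -> Model:
    """Lumped TCA segment for the AKGDHC inhibition study.

    A four-carbon carrier moiety cycles OAA → AKG → SCoA → OAA; pyruvate
    enters by condensing with OAA (lumping PDH + citrate synthase + IDH),
    AKGDHC catalyzes AKG + NAD⁺ → SCoA + NADH (the scanned reaction,
    RE103), AKG can leave to blood/urine (RE107) — which is what limits
    substrate-accumulation compensation under inhibition — and pyruvate
    carboxylase (RE108) replenishes the carrier pool.  Inhibiting RE103
    traps the carrier moiety as AKG, depletes OAA, throttles pyruvate entry
    and therefore raises the steady pyruvate level while the scanned flux
    and ATP generation fall — the diagnostic pattern of the deficiency.

    All rate scales and pool sizes (μM) are fixture-chosen nominal values.
    """
    ma = lambda V, *sids: RateLaw("mass_action", V=V, substrate_ids=sids)
    b = lambda sid, c, role="metabolite": Species(sid, compartment="mit",
                                                  initial_concentration=c, role=role,
                                                  boundary=True)
    species = [
        Species("Pyruvate", compartment="mit", initial_concentration=2.0,
                role="substrate"),
        Species("AKG", compartment="mit", initial_concentration=0.5,
                role="metabolite"),
        Species("SCoA", compartment="mit", initial_concentration=5.0,
                role="metabolite"),
        Species("OAA", compartment="mit", initial_concentration=5.0,
                role="metabolite"),
        Species("NAD", compartment="mit", initial_concentration=8.0,
                role="energy_currency"),
        Species("NADH", compartment="mit", initial_concentration=2.0,
                role="energy_currency"),
        Species("ATP", compartment="mit", initial_concentration=5.0,
                role="energy_currency"),
        Species("ADP", compartment="mit", initial_concentration=5.0,
                role="energy_currency"),
        b("PyrSrc", 1.0, "substrate"),
        b("Lactate", 0.0),
        b("AKGblood", 0.0),
        b("AKGDHC", 1.0, "enzyme"),
    ]
    reactions = [
        Reaction("RE100", reactants=(("PyrSrc", 1),), products=(("Pyruvate", 1),),
                 rate_law=RateLaw("saturation", V=1.0, Km=1.0,
                                  substrate_ids=("PyrSrc",)),
                 name="pyruvate supply"),
        Reaction("RE101", reactants=(("Pyruvate", 1), ("OAA", 1)),
                 products=(("AKG", 1),),
                 rate_law=ma(0.05, "Pyruvate", "OAA"),
                 name="pyruvate entry + citrate synthase + IDH (lumped)"),
        Reaction("RE102", reactants=(("Pyruvate", 1),), products=(("Lactate", 1),),
                 rate_law=ma(0.05, "Pyruvate"), name="lactate overflow"),
        Reaction("RE103", reactants=(("AKG", 1), ("NAD", 1)),
                 products=(("SCoA", 1), ("NADH", 1)),
                 modifiers=("AKGDHC",),
                 rate_law=ma(0.05, "AKG", "NAD"),
                 name="alpha-ketoglutarate dehydrogenase complex"),
        Reaction("RE104", reactants=(("SCoA", 1), ("ADP", 1)),
                 products=(("OAA", 1), ("ATP", 1)),
                 rate_law=ma(0.05, "SCoA", "ADP"),
                 name="succinyl-CoA → OAA (lumped, substrate-level ATP)"),
        Reaction("RE105", reactants=(("NADH", 1), ("ADP", 1)),
                 products=(("NAD", 1), ("ATP", 1)),
                 rate_law=ma(0.05, "NADH", "ADP"),
                 name="oxidative phosphorylation (lumped)"),
        Reaction("RE106", reactants=(("ATP", 1),), products=(("ADP", 1),),
                 rate_law=ma(0.1, "ATP"), name="ATPase load"),
        Reaction("RE107", reactants=(("AKG", 1),), products=(("AKGblood", 1),),
                 rate_law=ma(0.01, "AKG"), name="AKG efflux to blood/urine"),
        Reaction("RE108", reactants=(("Pyruvate", 1),), products=(("OAA", 1),),
                 rate_law=ma(0.01, "Pyruvate"),
                 name="pyruvate carboxylase (anaplerosis)"),
    ]
    return Model(
        id="tca_dldd",
        name="TCA segment around AKGDHC",
        compartments=_mito_compartments(),
        species=species,
        reactions=reactions,
        notes="Scan reaction: RE103 (AKGDHC).",
    )


def _build_beta_oxidation() -> Model:
    """C22 beta-oxidation with the carnitine shuttle, for the uremia study.

    Cytosolic C22 acyl-CoA is esterified to long-chain acylcarnitine (LCAC,
    RE200 = CPT-I), re-released in the matrix (RE201 = CPT-II), then
    dehydrogenated to C22 trans-enoyl-CoA (RE202), hydrated to C22
    L3-hydroxy-acyl-CoA (RE203) and oxidized with NAD⁺ (RE204); NADH is
    reoxidized by respiration (RE205).  The uremic scenario raises acyl-CoA,
    lowers free carnitine and scales down RE201/RE205.
    """
    ma = lambda V, *sids: RateLaw("mass_action", V=V, substrate_ids=sids)
    sat = lambda sid, km, V: RateLaw("saturation", V=V, Km=km, substrate_ids=(sid,))
    species = [
        Species("C22AcylCoA", compartment="cyt", initial_concentration=5.0,
                role="substrate"),
        Species("Carnitine", compartment="cyt", initial_concentration=10.0,
                role="carrier"),
        Species("LCAC", compartment="ims", initial_concentration=1.0,
                role="carrier"),
        Species("C22AcylCoAm", compartment="mit", initial_concentration=1.0,
                role="substrate"),
        Species("C22TransEnoylCoA", compartment="mit", initial_concentration=8.0,
                role="metabolite"),
        Species("C22L3HydroxyAcylCoA", compartment="mit", initial_concentration=0.5,
                role="metabolite"),
        Species("NAD", compartment="mit", initial_concentration=9.0,
                role="energy_currency"),
        Species("NADH", compartment="mit", initial_concentration=1.0,
                role="energy_currency"),
        Species("AcCoAout", compartment="mit", initial_concentration=0.0,
                role="metabolite", boundary=True),
    ]
    reactions = [
        Reaction("RE200", reactants=(("C22AcylCoA", 1), ("Carnitine", 1)),
                 products=(("LCAC", 1),),
                 rate_law=ma(0.02, "C22AcylCoA", "Carnitine"),
                 name="carnitine palmitoyltransferase I"),
        Reaction("RE201", reactants=(("LCAC", 1),),
                 products=(("C22AcylCoAm", 1), ("Carnitine", 1)),
                 rate_law=ma(0.05, "LCAC"),
                 name="carnitine palmitoyltransferase II"),
        Reaction("RE202", reactants=(("C22AcylCoAm", 1),),
                 products=(("C22TransEnoylCoA", 1),),
                 rate_law=sat("C22AcylCoAm", 5.0, 0.1),
                 name="acyl-CoA dehydrogenase"),
        Reaction("RE203", reactants=(("C22TransEnoylCoA", 1),),
                 products=(("C22L3HydroxyAcylCoA", 1),),
                 rate_law=sat("C22TransEnoylCoA", 5.0, 0.5),
                 name="enoyl-CoA hydratase"),
        Reaction("RE204", reactants=(("C22L3HydroxyAcylCoA", 1), ("NAD", 1)),
                 products=(("AcCoAout", 1), ("NADH", 1)),
                 rate_law=ma(0.01, "C22L3HydroxyAcylCoA", "NAD"),
                 name="L3-hydroxy-acyl-CoA dehydrogenase"),
        Reaction("RE205", reactants=(("NADH", 1),), products=(("NAD", 1),),
                 rate_law=ma(0.02, "NADH"),
                 name="respiratory NADH reoxidation (lumped)"),
    ]
    return Model(
        id="beta_oxidation",
        name="C22 beta-oxidation with carnitine shuttle",
        compartments=_mito_compartments(),
        species=species,
        reactions=reactions,
        notes="Uremia scenario scales RE201 and RE205 down.",
    )


_BUILDERS = {
    "glucose_block": _build_glucose_block,
    "core_energy": _build_core_energy,
    "phosphagen": _build_phosphagen,
    "tca_dldd": _build_tca_dldd,
    "beta_oxidation": _build_beta_oxidation,
}


def build_fixture(name: str) -> Model:
    """Build one of the named fixture models (fresh copy each call)."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return builder()


def random_network(n_species: int, n_reactions: int, seed: int) -> Model:
    """Seeded random connected model with unit stoichiometry.

    Reactions are A → B conversions with random saturation or mass-action
    laws; the first ``n_species − 1`` reactions form a chain so the network
    is connected.  Identical seed ⇒ bit-identical model; the output always
    passes :func:`kinemet.core.validate_model`.
    """
    if n_species < 2 or n_reactions < 1:
        raise ValueError("need n_species >= 2 and n_reactions >= 1")
    rng = random.Random(seed)
    sids = [f"S{i}" for i in range(n_species)]
    species = [
        Species(sid, compartment="cyt",
                initial_concentration=round(rng.uniform(0.5, 20.0), 3))
        for sid in sids
    ]
    reactions: list[Reaction] = []
    signatures: set[tuple] = set()
    j = 0
    attempts = 0
    while len(reactions) < n_reactions:
        attempts += 1
        if attempts > 100 * n_reactions:
            raise ValueError(
                f"cannot place {n_reactions} non-redundant reactions on "
                f"{n_species} species"
            )
        if len(reactions) < n_species - 1 and len(reactions) < n_reactions:
            a, b = len(reactions), len(reactions) + 1  # chain backbone
        else:
            a, b = rng.sample(range(n_species), 2)
        kind = rng.choice(["saturation", "mass_action"])
        sig = (frozenset({(sids[a], 1)}), frozenset({(sids[b], 1)}), kind)
        if sig in signatures:
            continue
        signatures.add(sig)
        if kind == "saturation":
            law = RateLaw("saturation", V=round(rng.uniform(0.5, 2.0), 3),
                          Km=round(rng.uniform(0.05, 50.0), 3),
                          substrate_ids=(sids[a],))
        else:
            law = RateLaw("mass_action", V=round(rng.uniform(0.01, 1.0), 3),
                          substrate_ids=(sids[a],))
        reactions.append(
            Reaction(f"R{j}", reactants=((sids[a], 1),), products=((sids[b], 1),),
                     rate_law=law, reversible=rng.random() < 0.3)
        )
        j += 1
    return Model(
        id=f"random_{n_species}x{n_reactions}_{seed}",
        name="random test network",
        compartments=[Compartment("cyt", "cytosol", "default")],
        species=species,
        reactions=reactions,
    )
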