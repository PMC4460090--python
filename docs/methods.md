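# Methods

## Model class

A model is a set of compartments (mitochondrion, inner membrane,
intermembrane space, outer membrane, or a default cytosol), species and
reactions. Species carry an initial concentration in μM and a `boundary`
flag: boundary species participate in rate laws but are clamped
(derivative pinned to zero), which is how external pools, sinks and
enzymes are represented. Reactions carry positive-integer stoichiometries
and exactly one of three kinetic laws:

- **saturation** — `V·x/(Km+x)`, the single-substrate Michaelis–Menten
  form used for nearly every enzymatic step in the energy-pool network;
- **mass action** — `V·x₁·x₂·…`, used for bimolecular couplings
  (kinase/phosphotransfer steps, NAD⁺-coupled dehydrogenations) and for
  first-order conversions;
- **constant** — a fixed flux `V`.

The default rate scale is `V = 1` per unit compartment volume, overridable
per reaction; compartment volumes default to 1 and rates are treated as
already amount-based, so no additional volume scaling is applied.
Multi-compartment transport therefore needs no special casing. Enzymes
enter as modifiers with clamped concentration; enzyme inhibition or
deficiency is modelled by scaling the affected reaction's `V` (equivalent
under V ∝ [E]).

Time is in seconds and concentrations in μM everywhere. Km values are used
numerically exactly as given, with no unit-conversion layer.

## Simulation and steady states

The right-hand side is `d[s]/dt = Σ_r N(s,r)·rate_r(state)` over
non-boundary species, with N the stoichiometric matrix (products positive,
reactants negative, boundary rows excluded). Integration uses LSODA with
relative tolerance 1e-8 and absolute tolerance 1e-12 μM, because fixture
concentrations span 1e-2 to 1e4 μM. Rate laws see concentrations clipped
at zero; trajectory values within ~1e-9 μM below zero are treated as
round-off and clipped. Per-reaction fluxes are recomputed from the stored
concentrations, so a trajectory's flux table is exactly consistent with
its concentration table.

`find_steady_state` first runs a Newton-type root find (MINPACK hybrd) on
the dynamic subspace from the supplied initial guess, then — if the
residual `max |dx/dt|` is not below 1e-9 μM/s, or the root is unphysical —
falls back to integration over doubling horizons (up to 1e8 s) until the
residual passes. The reported steady state carries both the residual and
`‖N·v‖∞`. Conserved-moiety directions make the Jacobian singular; the
hybrid strategy handles this because relaxation respects the conserved
totals of the initial condition. The inhibition scan deliberately relaxes
by integration *before* polishing, so every scan row reports the
physically attained steady state rather than an arbitrary algebraic root —
the rate laws are nonlinear enough to admit multiple roots.

## Stoichiometric analysis

Conservation relations are the left null space of N, computed exactly over
rationals (sympy) and scaled to coprime integer weights with a positive
leading entry. Elementary flux modes are computed by the classical tableau
(double-description) iteration over exact `Fraction` arithmetic:
reversible reactions are split into forward/backward columns, one
metabolite constraint is imposed per step with conic pairwise
combinations, non-minimal supports are pruned after each step, and the
spurious forward/backward 2-cycles are removed on recombination. Exact
arithmetic at this scale (a hard cap of 32 reactions, refused beyond that)
beats floating-point tableaux on reliability. Modes are normalized so the
smallest nonzero |weight| is 1 and ordered lexicographically by support,
making outputs directly comparable in tests. A brute-force oracle
(exhaustive support enumeration + null-space dimension + sign feasibility
+ minimality) lives alongside and is what the equivalence tests compare
against; when a mode's support is entirely reversible, both orientations
are reported, matching the split-column convention.

## Reduced ODEs and condition factors

Freezing every non-focal species at a reference state collapses the focal
metabolite's rate equation to `dY/dx = αx + β + Σ aᵢ·x/(Kᵢ+x)`:
saturation terms in the focal species keep their x-dependence (signed by
stoichiometry), mass-action terms linear in the focal species contribute
to α, and everything else evaluates to the constant β. Terms where the
focal species enters nonlinearly are refused rather than approximated.

The antiderivative is exact:
`Y(x) = (α/2)x² + (β+Σaᵢ)x − Σ aᵢKᵢ·log(x+Kᵢ) + C₁`, with log the natural
logarithm (the antiderivative of `1/(x+K)` forces ln). Coefficients keep
the numeric type they were given, so over `Fraction` inputs
differentiate∘antiderivative is an exact structural identity — this is
property-tested, with sympy as an independent symbolic cross-check.

The condition factors are read off the closed form: for the glucose,
starvation and exercise conditions the factor is the linear coefficient
`β + Σaᵢ` (defined only when α = 0); for obesity it is the common
multiplier c of the factored form `c·(x − log(x+1))`, and extraction fails
loudly when linear and log coefficients are not proportional that way.
Two conventions worth noting:

- Published displays of such closed forms sometimes omit the `·x` on the
  linear term (e.g. "−2.1586 + 0.048·log(x+0.048)"); the mathematically
  forced form `−2.1586·x + 0.048·log(x+0.048) + C₁` is what this package
  produces, and the factor value is unaffected.
- The reduced ATP equation's coefficients α = −57.4, β = −3.207 are not
  derivable from the information in scope (the frozen concentrations
  behind them are unpublished); they are stored as printed-underived
  constants in `kinemet.fixtures.CONSTANTS` and used as inputs, never
  recomputed. Likewise the hypoglycaemic glucose factor displays as
  0.9998 in four-decimal truncation while the computed value is
  0.999880…; comparisons use relative tolerance, not string equality.

## Scenarios

A scenario is a named, pure transformation: initial-concentration
overrides plus per-reaction V scalings, applied to a copy. Built-ins:

| scenario | definition |
|---|---|
| normal | identity |
| hypoglycaemic / hyperglycaemic | glucose initial 400 / 11100 μM (the "more than 11100" state is fixed at exactly 11100 for reproducibility) |
| starvation / exercise / obesity | focal reduced-ODE conditions (glucose, acetyl-CoA at Km 40, triglyceride with the −2x/(1+x) drain); their β constants are stored inputs |
| uremia | C22 acyl-CoA ↑ (15 μM), free carnitine ↓ (2 μM), CPT-II scaled ×0.2, respiratory NADH reoxidation ×0.1 |
| dldd | AKGDHC reaction V scaled; the scan applies V·(1−f) for f ∈ {0.2, 0.4, 0.6, 0.8, 0.95} plus an always-present f = 0 baseline |

Readouts from trajectories: final LCAC/free-carnitine ratio, NADH/NAD⁺ and
ATP net changes, and the Pearson correlation of C22 trans-enoyl-CoA with
C22 L3-hydroxy-acyl-CoA. Readouts naming species absent from the model are
reported as `"unavailable"`, not raised.

## Fixture networks — what they emulate and what they do not

The full curated 173-reaction / 158-metabolite energy-pool model is not
redistributable, so five programmatic fixtures realize the printed
subnetworks; they are first-class tested code, exportable as SBML.

- **glucose_block / core_energy** — the seven-reaction glucose
  neighbourhood (limit dextrin, sucrose, trehalose, two lactose routes,
  glucose-6-phosphatase in; hexokinase out, Km 0.048 μM) and the ATP
  neighbourhood with ATP consumed in RE25/RE27/RE34/RE36/RE79/RE84/RE88
  and produced in RE28/RE31. Boundary concentrations for pools whose
  values were never published are fixture-chosen nominal values, picked
  once so that total inflow stays below the saturating consumer's capacity
  and a steady state exists; every quantitative claim in the tests is
  independent of these choices.
- **phosphagen** — the closed creatine-kinase buffer (RE182
  forward/backward); its ATP+ADP and Cr+CrP moiety conservation is the
  substrate for conservation-law tests.
- **tca_dldd** — a lumped TCA segment in which a four-carbon carrier
  moiety cycles OAA → AKG → SCoA → OAA. Pyruvate enters by condensing with
  OAA (lumping PDH, citrate synthase and IDH), AKGDHC catalyzes
  AKG + NAD⁺ → SCoA + NADH, succinyl-CoA regenerates OAA with
  substrate-level phosphorylation, NADH feeds a lumped oxidative
  phosphorylation, and two physiological escape valves — lactate overflow
  and AKG efflux to blood/urine, balanced by pyruvate-carboxylase
  anaplerosis — keep the system away from degenerate steady states. The
  efflux is what limits substrate-accumulation compensation: inhibiting
  AKGDHC traps the carrier pool as AKG, depletes OAA, throttles pyruvate
  entry, and so raises steady pyruvate while the scanned flux and ATP
  generation fall. These directional outcomes are structural (they follow
  from the topology), not tuned.
- **beta_oxidation** — C22 acyl-CoA through the carnitine shuttle (CPT-I,
  CPT-II) into the dehydrogenation → hydration → NAD⁺-linked oxidation
  steps of beta-oxidation.

What passing tests therefore show: the machinery (assembly, integration,
steady states, exact structural analysis, reduction, scenario logic) is
correct on networks with the printed kinetics and topology, and the
disease scenarios reproduce the qualitative/directional patterns. What
they do not show: quantitative agreement of figure-level trajectories of
the full 173-reaction model (timings such as flux plateaus within
hundredths of a second depend on the unavailable full parameterization and
are treated as qualitative shape checks only).

`random_network(n_species, n_reactions, seed)` builds seeded,
validating, connected unit-stoichiometry models (chain backbone plus
random extra conversions, random saturation/mass-action laws, ~30 %
reversible) as the substrate for oracle-equivalence testing.

## Numerical choices and limitations

- Integration: LSODA, rtol 1e-8, atol 1e-12 μM; steady-state residual
  tolerance 1e-9 μM/s — below any displayed precision in scope.
- Exactness boundary: structural analysis (N, conservation, EFMs,
  reduction round trip) is exact rational arithmetic; simulation is IEEE
  double with the tolerances above.
- Display rounding for comparisons against published values follows each
  value's printed precision (4 decimals for the hypoglycaemic factor, 8
  for the hyperglycaemic, 1 for the glucose-integral coefficient), with
  relative-tolerance comparisons (1e-3 / 1e-6) rather than string
  equality.
- SBML: documents are emitted as Level 2 Version 4 with kinetic laws as
  self-contained MathML over local parameters V (and Km); read-side
  pattern matching accepts any expression algebraically equal to one of
  the three kinds and rejects everything else naming the reaction. Unknown
  namespaces (e.g. CellDesigner extensions) are dropped on read —
  simulation semantics are unaffected — and not preserved on re-write.
- Not in scope: thermodynamic feasibility, reversible mass-action
  equilibrium constraints, stochastic or delay dynamics, parameter
  fitting, genome-scale flux-mode performance, and SBML layout/render.

## Problem sizes used in the checked results

The packaged checks run the oracle-equivalence comparison on 200 seeded
random networks of up to 8 reactions, the reduction round-trip identity on
1000 random `Fraction`-valued reduced ODEs, the inhibition scan on the
fraction grid {0, 0.2, 0.4, 0.6, 0.8, 0.95}, and trajectory readouts on
50–400 s windows of the fixtures — sizes at which the exact algorithms are
effectively instantaneous while still exercising every code path.
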