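"""Scenario engine: named physiological/disease conditions as
override-plus-readout bundles.

A :class:`Scenario` is a pure transformation of a model — initial
concentration overrides plus per-reaction V scalings (enzyme inhibition is
V·(1−f), equivalent to lowering enzyme concentration since V ∝ [E]).  The
built-in scenarios are the seven conditions the energy-pool study tests:
hypo/hyperglycaemia (glucose clamped at 400 / 11100 μM), starvation,
exercise, obesity (focal reduced-ODE conditions), uremia (impaired
carnitine shuttle and respiration) and DLDD (AKGDHC inhibition), plus
"normal" (identity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

from .core import Model, ModelError
from .engine import ConvergenceError, SteadyState, Trajectory, find_steady_state
from .fixtures import CONSTANTS

__all__ = [
    "Scenario",
    "ScanResult",
    "SCENARIO_NAMES",
    "builtin_scenario",
    "apply_scenario",
    "dldd_inhibition_scan",
    "scenario_readouts",
    "load_scenario_config",
]

SCENARIO_NAMES = (
    "normal",
    "hypoglycaemic",
    "hyperglycaemic",
    "starvation",
    "exercise",
    "obesity",
    "uremia",
    "dldd",
)

DEFAULT_DLDD_FRACTIONS = (0.2, 0.4, 0.6, 0.8, 0.95)


@dataclass
class Scenario:
    name: str
    initial_overrides: dict[str, float] = field(default_factory=dict)
    v_scalings: dict[str, float] = field(default_factory=dict)
    focal: str | None = None
    readouts: tuple[str, ...] = ()

    def validate_against(self, model: Model) -> None:
        known_sp = set(model.species_ids)
        for sid in self.initial_overrides:
            if sid not in known_sp:
                raise ModelError(f"scenario override references unknown species {sid!r}")
        known_rxn = set(model.reaction_ids)
        for rid, scale in self.v_scalings.items():
            if rid not in known_rxn:
                raise ModelError(f"scenario scaling references unknown reaction {rid!r}")
            if scale < 0:
                raise ModelError(f"scenario scaling for {rid} must be >= 0")


def builtin_scenario(name: str) -> Scenario:
    """The named built-in condition (fresh copy)."""
    c = CONSTANTS
    table: dict[str, Scenario] = {
        "normal": Scenario("normal"),
        "hypoglycaemic": Scenario(
            "hypoglycaemic",
            initial_overrides={"Glucose": c.hypoglycaemic_glucose},
            focal="Glucose",
        ),
        "hyperglycaemic": Scenario(
            "hyperglycaemic",
            initial_overrides={"Glucose": c.hyperglycaemic_glucose},
            focal="Glucose",
        ),
        "starvation": Scenario("starvation", focal="Glucose"),
        "exercise": Scenario("exercise", focal="AcetylCoA"),
        "obesity": Scenario("obesity", focal="Triglyceride"),
        "uremia": Scenario(
            "uremia",
            initial_overrides={"C22AcylCoA": 15.0, "Carnitine": 2.0},
            v_scalings={"RE201": 0.2, "RE205": 0.1},
            readouts=("lcac_carnitine_ratio", "nadh_net_change", "nad_net_change",
                      "c22_correlation"),
        ),
        "dldd": Scenario(
            "dldd",
            v_scalings={"RE103": 0.5},
            readouts=("atp_net_change",),
        ),
    }
    try:
        return table[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; available: {', '.join(SCENARIO_NAMES)}"
        ) from None


def apply_scenario(model: Model, scenario: Scenario) -> Model:
    """Return a modified copy of the model; the original is untouched."""
    scenario.validate_against(model)
    out = model.copy()
    for sid, conc in scenario.initial_overrides.items():
        out.species_by_id(sid).initial_concentration = float(conc)
    for rid, scale in scenario.v_scalings.items():
        rxn = out.reaction_by_id(rid)
        rxn.rate_law.V = rxn.rate_law.V * float(scale)
    return out


@dataclass
class ScanResult:
    """Steady-state responses over a grid of inhibition fractions.

    Row 0 (fraction 0) is the unmodified baseline.  ``None`` entries mark
    fractions where the steady-state search failed.
    """

    reaction_id: str
    fractions: list[float]
    scanned_flux: list[float | None]
    atp_generation: list[float | None]
    pyruvate: list[float | None]
    failures: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fraction": self.fractions,
            "scanned_flux": self.scanned_flux,
            "atp_generation": self.atp_generation,
            "pyruvate": self.pyruvate,
        })


def _atp_generation_rate(model: Model, ss: SteadyState) -> float:
    """Sum of ATP-producing flux contributions at steady state (μM/s)."""
    total = 0.0
    for rxn in model.reactions:
        n = rxn.net_stoichiometry("ATP")
        if n > 0:
            total += n * ss.fluxes[rxn.id]
    return total


def dldd_inhibition_scan(
    model: Model,
    reaction: str = "RE103",
    fractions: Sequence[float] = DEFAULT_DLDD_FRACTIONS,
) -> ScanResult:
    """Steady-state scan of fractional inhibition of one reaction.

    For each fraction f the reaction's V is scaled by (1−f) and the steady
    state recomputed; a baseline row (f = 0) is always first.  Reports the
    scanned reaction's flux, the ATP-generation rate and the steady
    pyruvate level.
    """
    model.reaction_by_id(reaction)  # raises KeyError for unknown reactions
    fr = list(fractions)
    if any(f < 0 or f > 1 for f in fr):
        raise ValueError("inhibition fractions must lie in [0, 1]")
    if 0.0 not in fr:
        fr = [0.0, *fr]
    fr.sort()
    result = ScanResult(reaction, fr, [], [], [])
    has_pyruvate = "Pyruvate" in model.species_ids
    for f in fr:
        scen = Scenario(f"inhibition_{f}", v_scalings={reaction: 1.0 - f})
        m = apply_scenario(model, scen)
        try:
            # relax toward the attractor first so the Newton polish lands on
            # the physically reached steady state at every fraction
            from .engine import simulate_time_course

            relaxed = simulate_time_course(m, t_end=5000.0, n_points=2)
            guess = {
                sid: float(relaxed.concentrations[sid].iloc[-1])
                for sid in m.species_ids
            }
            ss = find_steady_state(m, initial=guess)
        except ConvergenceError as exc:
            result.scanned_flux.append(None)
            result.atp_generation.append(None)
            result.pyruvate.append(None)
            result.failures.append(f"fraction {f}: {exc}")
            continue
        result.scanned_flux.append(ss.fluxes[reaction])
        result.atp_generation.append(_atp_generation_rate(m, ss))
        result.pyruvate.append(ss.concentrations["Pyruvate"] if has_pyruvate else None)
    return result


READOUT_NAMES = (
    "lcac_carnitine_ratio",
    "nadh_net_change",
    "nad_net_change",
    "atp_net_change",
    "c22_correlation",
)

_READOUT_SPECIES = {
    "lcac_carnitine_ratio": ("LCAC", "Carnitine"),
    "nadh_net_change": ("NADH",),
    "nad_net_change": ("NAD",),
    "atp_net_change": ("ATP",),
    "c22_correlation": ("C22TransEnoylCoA", "C22L3HydroxyAcylCoA"),
}


def scenario_readouts(
    trajectory: Trajectory,
    scenario: Scenario | None = None,
    readouts: Iterable[str] = READOUT_NAMES,
) -> dict[str, float | str]:
    """Compute named readouts from a trajectory.

    Readouts referencing species absent from the model are reported as the
    string ``"unavailable"`` rather than raising.  ``c22_correlation`` is
    the Pearson correlation of the two C22 beta-oxidation intermediates over
    the trajectory (0.0 when either series is constant).
    """
    conc = trajectory.concentrations
    out: dict[str, float | str] = {}
    wanted = tuple(readouts)
    if scenario is not None and scenario.readouts:
        wanted = scenario.readouts
    for name in wanted:
        needed = _READOUT_SPECIES.get(name)
        if needed is None:
            raise ValueError(f"unknown readout {name!r}")
        if any(s not in conc.columns for s in needed):
            out[name] = "unavailable"
            continue
        if name == "lcac_carnitine_ratio":
            out[name] = float(conc["LCAC"].iloc[-1] / conc["Carnitine"].iloc[-1])
        elif name.endswith("_net_change"):
            (sid,) = needed
            out[name] = trajectory.net_change(sid)
        else:  # c22_correlation
            a = conc["C22TransEnoylCoA"].to_numpy()
            b = conc["C22L3HydroxyAcylCoA"].to_numpy()
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                out[name] = 0.0
            else:
                out[name] = float(np.corrcoef(a, b)[0, 1])
    return out


def load_scenario_config(stream: TextIO | str) -> Scenario:
    """Load a scenario from a plain-text ``key: value`` config.

    Recognized keys: ``name``, ``focal``, ``override.<species>``,
    ``scale.<reaction>``, ``readout`` (repeatable).  Lines starting with
    ``#`` and blank lines are ignored.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    name = "custom"
    overrides: dict[str, float] = {}
    scalings: dict[str, float] = {}
    focal: str | None = None
    readouts: list[str] = []
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"line {lineno}: expected 'key: value', got {raw!r}")
        key, value = (part.strip() for part in line.split(":", 1))
        if key == "name":
            name = value
        elif key == "focal":
            focal = value
        elif key == "readout":
            readouts.append(value)
        elif key.startswith("override."):
            overrides[key[len("override."):]] = float(value)
        elif key.startswith("scale."):
            scalings[key[len("scale."):]] = float(value)
        else:
            raise ValueError(f"line {lineno}: unknown key {key!r}")
    return Scenario(name=name, initial_overrides=overrides, v_scalings=scalings,
                    focal=focal, readouts=tuple(readouts))
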