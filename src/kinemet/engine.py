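"""ODE assembly, time-course simulation, steady states and fluxes.

The right-hand side of the system is d[s]/dt = Σ_r N(s,r)·rate_r(state) for
every non-boundary species s; boundary species are clamped (derivative 0).
Integration uses a stiff solver (LSODA) with tight tolerances because the
fixture networks span concentrations from 1e-2 to 1e4 μM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .core import Model, ModelError, stoichiometric_matrix

__all__ = [
    "Trajectory",
    "SteadyState",
    "IntegrationError",
    "ConvergenceError",
    "saturation_term",
    "assemble_rhs",
    "simulate_time_course",
    "find_steady_state",
]

RTOL = 1e-8       # relative integration tolerance
ATOL = 1e-12      # absolute tolerance, μM
SS_TOL = 1e-9     # steady state: max |dx/dt| below this, μM/s


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the last valid time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


class ConvergenceError(RuntimeError):
    """Steady-state search failed; carries the best residual found."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


def saturation_term(x: float, Km: float, V: float = 1.0) -> float:
    """Michaelis–Menten rate V·x/(Km+x) (μM/s).

    Strictly increasing in x, bounded above by V; Km is the substrate
    concentration at half-maximal rate.
    """
    if x < 0 or Km <= 0 or V <= 0:
        raise ValueError(
            f"saturation_term requires x >= 0, Km > 0, V > 0 (got x={x}, Km={Km}, V={V})"
        )
    return V * x / (Km + x)


@dataclass
class Trajectory:
    """Uniform time grid with per-species concentrations and per-reaction fluxes."""

    times: np.ndarray                       # seconds, strictly increasing
    concentrations: pd.DataFrame            # one column per non-boundary (and boundary) species, μM
    fluxes: pd.DataFrame                    # one column per reaction, μM/s

    def final(self, species_id: str) -> float:
        return float(self.concentrations[species_id].iloc[-1])

    def net_change(self, species_id: str) -> float:
        col = self.concentrations[species_id]
        return float(col.iloc[-1] - col.iloc[0])

    def to_csv(self, path) -> None:
        """CSV with header time,<species...>,<flux:reaction...>."""
        df = self.concentrations.copy()
        df.insert(0, "time", self.times)
        for rid in self.fluxes.columns:
            df[f"flux:{rid}"] = self.fluxes[rid].to_numpy()
        df.to_csv(path, index=False)


@dataclass
class SteadyState:
    concentrations: dict[str, float]
    fluxes: dict[str, float]
    residual: float                 # max |dx/dt|, μM/s
    nv_residual: float              # max |N·v|

    def flux(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


def _compiled_system(model: Model):
    """Shared machinery: species order, N over dynamic species, flux evaluator."""
    sids = model.species_ids
    index = {s: i for i, s in enumerate(sids)}
    dyn_mask = np.array([not s.boundary for s in model.species])
    N = np.zeros((len(sids), len(model.reactions)))
    laws = []
    for j, rxn in enumerate(model.reactions):
        for sid, n in rxn.reactants:
            N[index[sid], j] -= n
        for sid, n in rxn.products:
            N[index[sid], j] += n
        law = rxn.rate_law
        try:
            sub_idx = tuple(index[s] for s in law.substrate_ids)
        except KeyError as exc:
            raise ModelError(
                f"reaction {rxn.id!r} rate law references missing species {exc.args[0]!r}"
            ) from exc
        laws.append((law.kind, float(law.V), law.Km, sub_idx))
    N[~dyn_mask, :] = 0.0  # clamp boundary species

    def fluxes(y: np.ndarray) -> np.ndarray:
        v = np.empty(len(laws))
        yc = np.maximum(y, 0.0)  # rate laws see concentrations clipped at 0
        for j, (kind, V, Km, sub) in enumerate(laws):
            if kind == "constant":
                v[j] = V
            elif kind == "saturation":
                x = yc[sub[0]]
                v[j] = V * x / (Km + x)
            else:
                r = V
                for i in sub:
                    r *= yc[i]
                v[j] = r
        return v

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        return N @ fluxes(y)

    return sids, dyn_mask, N, fluxes, rhs


def assemble_rhs(model: Model) -> Callable[[Mapping[str, float]], dict[str, float]]:
    """Return the derivative function state ↦ d(state)/dt as species-id maps.

    Boundary species always get derivative 0.
    """
    sids, _dyn, _N, _fluxes, rhs = _compiled_system(model)

    def deriv(state: Mapping[str, float]) -> dict[str, float]:
        y = np.array([state[s] for s in sids], dtype=float)
        dy = rhs(0.0, y)
        return dict(zip(sids, dy.tolist()))

    return deriv


def simulate_time_course(
    model: Model,
    t_end: float,
    n_points: int = 101,
    overrides: Mapping[str, float] | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate the model ODEs on a uniform grid of ``n_points`` times.

    Deterministic given model + overrides + tolerances.  Raises
    :class:`IntegrationError` (with the last valid time) on solver failure.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    sids, _dyn, _N, fluxes, rhs = _compiled_system(model)
    state0 = model.initial_state(overrides)
    y0 = np.array([state0[s] for s in sids])
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(f"integration failed: {sol.message}", last)
    Y = sol.y.T  # (n_points, n_species)
    # clip tiny negative excursions (within absolute tolerance)
    small = (Y < 0) & (Y > -1e3 * atol)
    Y = np.where(small, 0.0, Y)
    conc = pd.DataFrame(Y, columns=sids)
    V = np.vstack([fluxes(y) for y in Y])
    flux = pd.DataFrame(V, columns=model.reaction_ids)
    return Trajectory(times=t_eval, concentrations=conc, fluxes=flux)


def find_steady_state(
    model: Model,
    initial: Mapping[str, float] | None = None,
    tol: float = SS_TOL,
    max_horizon: float = 1e8,
) -> SteadyState:
    """Locate a steady state: Newton from the initial guess, falling back to
    long-horizon integration until max |dx/dt| < tol.

    Reports per-reaction fluxes and the ‖N·v‖∞ residual over non-boundary
    species.  Raises :class:`ConvergenceError` if both strategies fail.
    """
    sids, dyn_mask, N, fluxes, rhs = _compiled_system(model)
    state0 = model.initial_state(initial)
    y0 = np.array([state0[s] for s in sids])

    def residual_of(y: np.ndarray) -> float:
        return float(np.max(np.abs(rhs(0.0, y)))) if y.size else 0.0

    best_y, best_res = y0, residual_of(y0)

    # damped-Newton style root find on the dynamic subspace
    dyn_idx = np.where(dyn_mask)[0]
    if dyn_idx.size:
        def f(yd: np.ndarray) -> np.ndarray:
            y = y0.copy()
            y[dyn_idx] = yd
            return rhs(0.0, y)[dyn_idx]

        try:
            res = root(f, y0[dyn_idx], method="hybr")
            y_try = y0.copy()
            y_try[dyn_idx] = res.x
            if np.all(y_try >= -ATOL):
                y_try = np.maximum(y_try, 0.0)
                r = residual_of(y_try)
                if r < best_res:
                    best_y, best_res = y_try, r
        except Exception:
            pass

    if best_res >= tol:
        # integration fallback with doubling horizons
        y = y0.copy()
        horizon = 10.0
        while horizon <= max_horizon:
            sol = solve_ivp(rhs, (0.0, horizon), y, method="LSODA",
                            rtol=RTOL, atol=ATOL)
            if not sol.success:
                break
            y = np.maximum(sol.y[:, -1], 0.0)
            r = residual_of(y)
            if r < best_res:
                best_y, best_res = y.copy(), r
            if r < tol:
                break
            horizon *= 10.0

    if best_res >= tol:
        raise ConvergenceError(
            f"steady-state search did not converge (residual {best_res:.3e})",
            best_res,
        )
    v = fluxes(best_y)
    nv = float(np.max(np.abs(N @ v))) if v.size else 0.0
    return SteadyState(
        concentrations=dict(zip(sids, best_y.tolist())),
        fluxes=dict(zip(model.reaction_ids, v.tolist())),
        residual=best_res,
        nv_residual=nv,
    )
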