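"""Collapse a focal species' rate equation to a scalar reduced ODE and
integrate it in closed form.

The full network ODE for a focal concentration x, with every other species
frozen at a reference state, always collapses (for the three supported rate
laws) to

    dY/dx = alpha·x + beta + Σ_i a_i·x/(K_i + x)

whose antiderivative is

    Y(x) = (alpha/2)·x² + (beta + Σ_i a_i)·x + Σ_i (−a_i·K_i)·log(x + K_i) + C1

with natural logarithm (the antiderivative of 1/(x+K) forces ln).  The
linear coefficient beta + Σ a_i is the "condition factor" named after the
physiological state the reduction was taken in (glucose, starvation,
exercise); the obesity factor is the common multiplier c when the closed
form factors as c·(x − log(x+1)).

Coefficients are kept as the numeric type supplied (float or
:class:`fractions.Fraction`), so with Fraction inputs the
differentiate∘antiderivative round trip is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Number
from typing import Mapping, Sequence

import sympy

from .core import Model, ModelError

__all__ = [
    "ReducedODE",
    "ClosedForm",
    "ConditionFactor",
    "ReductionError",
    "reduce_focal_ode",
    "antiderivative",
    "extract_condition_factor",
]

FACTOR_NAMES = {"glucose", "starvation", "exercise", "obesity"}


class ReductionError(ValueError):
    """Focal species enters a rate law in an unsupported (non-collapsible) way."""


@dataclass
class ReducedODE:
    """dY/dx = alpha·x + beta + Σ a·x/(K+x) for the focal species x."""

    focal: str
    alpha: Number = 0
    beta: Number = 0
    sat_terms: tuple[tuple[Number, Number], ...] = ()   # (a, K), K > 0
    frozen_state: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sat_terms = tuple(self.sat_terms)
        for _a, K in self.sat_terms:
            if K <= 0:
                raise ValueError("saturation term requires K > 0")

    def __call__(self, x: Number) -> Number:
        val = self.alpha * x + self.beta
        for a, K in self.sat_terms:
            val += a * x / (K + x)
        return val

    def as_sympy(self) -> sympy.Expr:
        x = sympy.Symbol("x")
        expr = sympy.sympify(self.alpha) * x + sympy.sympify(self.beta)
        for a, K in self.sat_terms:
            expr += sympy.sympify(a) * x / (sympy.sympify(K) + x)
        return expr


@dataclass
class ClosedForm:
    """Y(x) = quadratic·x² + linear·x + Σ coeff·log(x+K) + C1."""

    quadratic: Number = 0
    linear: Number = 0
    log_terms: tuple[tuple[Number, Number], ...] = ()   # (coefficient, offset K)

    def __post_init__(self) -> None:
        self.log_terms = tuple(self.log_terms)

    def __call__(self, x: float) -> float:
        import math

        val = self.quadratic * x * x + self.linear * x
        for c, K in self.log_terms:
            val += c * math.log(x + K)
        return val

    def derivative(self) -> ReducedODE:
        """Symbolic differentiation back to a reduced ODE (exact over Fractions).

        d/dx [q x² + l x + Σ c·log(x+K)] = 2q x + l + Σ c/(x+K); rewriting
        c/(x+K) = (c/K) − (c/K)·x/(K+x)·… recovers a = −c/K and
        beta = l − Σ a.
        """
        sat = tuple((-(c / K), K) for c, K in self.log_terms)
        beta = self.linear
        for a, _K in sat:
            beta = beta - a
        return ReducedODE(focal="x", alpha=2 * self.quadratic, beta=beta,
                          sat_terms=sat)

    def as_sympy(self) -> sympy.Expr:
        x = sympy.Symbol("x")
        expr = sympy.sympify(self.quadratic) * x**2 + sympy.sympify(self.linear) * x
        for c, K in self.log_terms:
            expr += sympy.sympify(c) * sympy.log(x + sympy.sympify(K))
        return expr

    def __str__(self) -> str:
        parts = []
        if self.quadratic:
            parts.append(f"{float(self.quadratic):g}*x^2")
        parts.append(f"{float(self.linear):g}*x")
        for c, K in self.log_terms:
            parts.append(f"{float(c):g}*log(x + {float(K):g})")
        body = " + ".join(parts).replace("+ -", "- ")
        return f"{body} + C1"


@dataclass
class ConditionFactor:
    name: str
    value: Number
    provenance: ReducedODE | None = None


def reduce_focal_ode(
    model: Model, focal: str, frozen: Mapping[str, float]
) -> ReducedODE:
    """Collapse the full-model ODE of ``focal`` to a scalar reduced form.

    Every reaction term containing the focal species with a saturation law
    in the focal substrate contributes (a, K) to ``sat_terms``; mass-action
    terms linear in focal contribute to ``alpha``; terms not involving focal
    are evaluated at ``frozen`` and summed into ``beta``.  Signs follow the
    focal species' net stoichiometry.
    """
    sp = model.species_by_id(focal)
    if sp.boundary:
        raise ReductionError(f"focal species {focal!r} is boundary (clamped)")
    alpha: Number = 0
    beta: Number = 0
    sat: list[tuple[Number, Number]] = []
    for rxn in model.reactions:
        n = rxn.net_stoichiometry(focal)
        if n == 0:
            continue
        law = rxn.rate_law
        if law.kind == "constant":
            beta += n * law.V
        elif law.kind == "saturation":
            (sid,) = law.substrate_ids
            if sid == focal:
                sat.append((n * law.V, law.Km))
            else:
                if sid not in frozen:
                    raise ReductionError(
                        f"frozen state missing species {sid!r} (reaction {rxn.id})"
                    )
                beta += n * law.V * frozen[sid] / (law.Km + frozen[sid])
        else:  # mass_action
            focal_power = sum(1 for s in law.substrate_ids if s == focal)
            if focal_power > 1:
                raise ReductionError(
                    f"reaction {rxn.id}: focal species appears nonlinearly "
                    "in a mass-action law"
                )
            coeff: Number = n * law.V
            for s in law.substrate_ids:
                if s == focal:
                    continue
                if s not in frozen:
                    raise ReductionError(
                        f"frozen state missing species {s!r} (reaction {rxn.id})"
                    )
                coeff *= frozen[s]
            if focal_power == 1:
                alpha += coeff
            else:
                beta += coeff
    return ReducedODE(
        focal=focal,
        alpha=alpha,
        beta=beta,
        sat_terms=tuple(sat),
        frozen_state=dict(frozen),
    )


def antiderivative(reduced: ReducedODE) -> ClosedForm:
    """Closed-form integral of the reduced ODE.

    ∫ a·x/(K+x) dx = a·x − a·K·log(x+K), so the quadratic coefficient is
    alpha/2, the linear coefficient is beta + Σ a_i, and each saturation
    term yields one log term (−a_i·K_i, K_i).  Symbolic differentiation
    round-trips exactly.
    """
    linear = reduced.beta
    logs = []
    for a, K in reduced.sat_terms:
        linear = linear + a
        logs.append((-(a * K), K))
    half = Fraction(1, 2) if isinstance(reduced.alpha, (int, Fraction)) else 0.5
    return ClosedForm(
        quadratic=reduced.alpha * half,
        linear=linear,
        log_terms=tuple(logs),
    )


def extract_condition_factor(closed: ClosedForm, name: str) -> ConditionFactor:
    """Pull the named condition factor out of a closed-form integral.

    glucose / starvation / exercise: the linear coefficient (requires no
    quadratic part).  obesity: the common multiplier c after factoring the
    closed form as c·(x − log(x+1)); raises :class:`ReductionError` when the
    linear and log coefficients are not proportional that way.
    """
    if name not in FACTOR_NAMES:
        raise ValueError(f"unknown condition factor {name!r}; one of {sorted(FACTOR_NAMES)}")
    if name == "obesity":
        c = closed.linear
        if closed.quadratic != 0 or not closed.log_terms:
            raise ReductionError("obesity factor requires a pure x − log(x+K) form")
        for coeff, _K in closed.log_terms:
            if coeff != -c:
                raise ReductionError(
                    "closed form does not factor as c*(x - log(x+K)): "
                    f"log coefficient {coeff} != {-c}"
                )
        return ConditionFactor(name=name, value=c)
    if closed.quadratic != 0:
        raise ReductionError(
            f"{name} factor defined for linear (quadratic-free) closed forms"
        )
    return ConditionFactor(name=name, value=closed.linear)
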