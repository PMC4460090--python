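"""Reduced scalar ODEs, closed-form antiderivatives and condition factors."""

import math
from fractions import Fraction

import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from kinemet.fixtures import build_fixture
from kinemet.reduction import (
    ClosedForm,
    ReducedODE,
    ReductionError,
    antiderivative,
    extract_condition_factor,
    reduce_focal_ode,
)
from kinemet.scenarios import apply_scenario, builtin_scenario


fractions_st = st.fractions(
    min_value=Fraction(-100), max_value=Fraction(100), max_denominator=50
)
pos_fractions_st = st.fractions(
    min_value=Fraction(1, 50), max_value=Fraction(100), max_denominator=50
)


def random_reduced(draw_alpha, draw_beta, sat):
    return ReducedODE("x", alpha=draw_alpha, beta=draw_beta, sat_terms=tuple(sat))


class TestReduceFocalOde:
    def test_glucose_block_saturation_term(self):
        """The consuming hexokinase term appears as (a=−1, K=0.048)."""
        m = apply_scenario(build_fixture("glucose_block"),
                           builtin_scenario("hypoglycaemic"))
        frozen = {k: v for k, v in m.initial_state().items() if k != "Glucose"}
        red = reduce_focal_ode(m, "Glucose", frozen)
        assert red.alpha == 0
        assert (-1.0, 0.048) in [(float(a), float(K)) for a, K in red.sat_terms]

    def test_reduction_matches_full_model_derivative(self):
        """alpha·x + beta + Σ a·x/(K+x) at the initial focal concentration
        equals the full-model focal derivative at the frozen state."""
        from kinemet.engine import assemble_rhs

        for scen in ("hypoglycaemic", "hyperglycaemic"):
            m = apply_scenario(build_fixture("core_energy"), builtin_scenario(scen))
            state = m.initial_state()
            frozen = {k: v for k, v in state.items() if k != "Glucose"}
            red = reduce_focal_ode(m, "Glucose", frozen)
            full = assemble_rhs(m)(state)["Glucose"]
            assert float(red(state["Glucose"])) == pytest.approx(full, rel=1e-12)

    def test_mass_action_linear_in_focal_goes_to_alpha(self):
        m = apply_scenario(build_fixture("core_energy"), builtin_scenario("normal"))
        state = m.initial_state()
        frozen = {k: v for k, v in state.items() if k != "ATP"}
        red = reduce_focal_ode(m, "ATP", frozen)
        # RE27 (−[F6P][ATP]) and RE36 (−[PGA3][ATP]) both load alpha
        assert float(red.alpha) == pytest.approx(-(state["F6P"] + state["PGA3"]))
        from kinemet.engine import assemble_rhs

        assert float(red(state["ATP"])) == pytest.approx(
            assemble_rhs(m)(state)["ATP"], rel=1e-10
        )

    def test_isolated_species_reduces_to_zero(self, ab_closed):
        from kinemet.core import Species

        ab_closed.species.append(Species("Lonely", compartment="c"))
        red = reduce_focal_ode(ab_closed, "Lonely", {"A": 1.0, "B": 1.0})
        assert red.alpha == 0 and red.beta == 0 and red.sat_terms == ()

    def test_boundary_focal_rejected(self, fed_chain):
        with pytest.raises(ReductionError):
            reduce_focal_ode(fed_chain, "Src", {})


class TestAntiderivative:
    @pytest.mark.parametrize(
        "reduced, quadratic, linear, logs",
        [
            # starvation: linear coefficient −2.1586, log term 0.048·log(x+0.048)
            (ReducedODE("x", beta=-1.1586, sat_terms=((-1, 0.048),)),
             0.0, -2.1586, [(0.048, 0.048)]),
            # glycaemic ATP: −28.7x² − 4.2068x
            (ReducedODE("x", alpha=-57.4, beta=-4.2068), -28.7, -4.2068, []),
            # obesity: −2x + 2·log(x+1)
            (ReducedODE("x", sat_terms=((-2, 1),)), 0.0, -2.0, [(2.0, 1.0)]),
        ],
    )
    def test_printed_closed_forms(self, reduced, quadratic, linear, logs):
        closed = antiderivative(reduced)
        assert float(closed.quadratic) == pytest.approx(quadratic)
        assert float(closed.linear) == pytest.approx(linear)
        assert [(float(c), float(K)) for c, K in closed.log_terms] == [
            (pytest.approx(c), pytest.approx(K)) for c, K in logs
        ]

    def test_glucose_integral_linear_coefficient(self):
        closed = antiderivative(
            ReducedODE("x", beta=16282.5775, sat_terms=((-1, 0.048),))
        )
        assert round(float(closed.linear), 1) == 16281.6

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        alpha=fractions_st,
        beta=fractions_st,
        sats=st.lists(st.tuples(fractions_st, pos_fractions_st), max_size=4),
    )
    def test_differentiation_round_trips_exactly(self, alpha, beta, sats):
        red = ReducedODE("x", alpha=alpha, beta=beta, sat_terms=tuple(sats))
        back = antiderivative(red).derivative()
        assert back.alpha == red.alpha
        assert back.beta == red.beta
        assert back.sat_terms == red.sat_terms

    def test_symbolic_round_trip_via_sympy(self):
        """Independent cross-check: d/dx of the sympy closed form simplifies
        to the sympy reduced ODE."""
        red = ReducedODE("x", alpha=Fraction(3, 7), beta=Fraction(-5, 3),
                         sat_terms=((Fraction(-2, 5), Fraction(7, 2)),))
        closed = antiderivative(red)
        x = sympy.Symbol("x")
        diff = sympy.simplify(sympy.diff(closed.as_sympy(), x) - red.as_sympy())
        assert diff == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        beta=st.floats(-10, 10),
        a=st.floats(-5, 5),
        K=st.floats(0.01, 50),
        x1=st.floats(0.01, 1000),
    )
    def test_closed_form_matches_quadrature(self, beta, a, K, x1):
        """ClosedForm(x1) − ClosedForm(x0) equals adaptive quadrature of the
        reduced ODE."""
        red = ReducedODE("x", beta=beta, sat_terms=((a, K),))
        closed = antiderivative(red)
        x0 = 0.0
        numeric, err = quad(lambda t: float(red(t)), x0, x1, limit=200)
        exact = closed(x1) - closed(x0 + 0.0 if K > 0 else x0)
        assert exact == pytest.approx(numeric, rel=1e-7, abs=max(1e-9, 10 * err))


class TestConditionFactors:
    @pytest.mark.parametrize(
        "reduced, name, expected",
        [
            (ReducedODE("x", beta=-1.1586, sat_terms=((-1, 0.048),)),
             "starvation", -2.1586),
            (ReducedODE("x", beta=-0.9976, sat_terms=((-1, 40),)),
             "exercise", -1.9976),
            (ReducedODE("x", sat_terms=((-2, 1),)), "obesity", -2.0),
        ],
    )
    def test_printed_factors(self, reduced, name, expected):
        factor = extract_condition_factor(antiderivative(reduced), name)
        assert float(factor.value) == pytest.approx(expected)

    def test_glucose_factor_from_saturation(self):
        """The glucose factor at a stated concentration is the saturation
        term x/(Km+x) entering the reduced ATP equation."""
        from kinemet.engine import saturation_term

        hypo = saturation_term(400.0, 0.048)
        hyper = saturation_term(11100.0, 0.048)
        assert hypo == pytest.approx(0.9998, rel=1e-3)
        assert hyper == pytest.approx(0.99999568, rel=1e-6)

    def test_linear_factors_add(self):
        r1 = ReducedODE("x", beta=Fraction(-1), sat_terms=((Fraction(-1), Fraction(2)),))
        r2 = ReducedODE("x", beta=Fraction(-2), sat_terms=((Fraction(-3), Fraction(5)),))
        rsum = ReducedODE("x", beta=r1.beta + r2.beta,
                          sat_terms=r1.sat_terms + r2.sat_terms)
        f = lambda r: extract_condition_factor(antiderivative(r), "starvation").value
        assert f(rsum) == f(r1) + f(r2)

    def test_obesity_requires_factorable_form(self):
        closed = antiderivative(ReducedODE("x", sat_terms=((-2, 3),)))  # K != 1
        with pytest.raises(ReductionError):
            extract_condition_factor(closed, "obesity")

    def test_linear_factor_rejects_quadratic(self):
        closed = antiderivative(ReducedODE("x", alpha=-57.4, beta=-4.2068))
        with pytest.raises(ReductionError):
            extract_condition_factor(closed, "starvation")
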