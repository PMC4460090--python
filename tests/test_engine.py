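"""ODE assembly, time courses, steady states and flux consistency."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import bisect

from kinemet.core import RateLaw, Reaction
from kinemet.engine import (
    ConvergenceError,
    assemble_rhs,
    find_steady_state,
    saturation_term,
    simulate_time_course,
)
from kinemet.core import conservation_relations, stoichiometric_matrix
from kinemet.fixtures import KM, build_fixture
from kinemet.scenarios import apply_scenario, builtin_scenario

from conftest import simple_model


class TestSaturationTerm:
    @pytest.mark.parametrize(
        "x, km, expected, tol",
        [
            (400.0, 0.048, 0.9998800143982722, 1e-12),   # hypoglycaemic glucose
            (11100.0, 0.048, 0.9999956756943753, 1e-12),  # hyperglycaemic glucose
            (0.0, 0.048, 0.0, 0.0),
            (1.0, 1.0, 0.5, 0.0),
        ],
    )
    def test_values(self, x, km, expected, tol):
        assert saturation_term(x, km, 1.0) == pytest.approx(expected, abs=tol)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            saturation_term(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            saturation_term(1.0, -1.0, 1.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        x=st.floats(0.0, 1e6),
        dx=st.floats(1e-9, 1e3),
        km=st.floats(1e-6, 1e4),
        dk=st.floats(1e-9, 1e3),
        v=st.floats(1e-6, 1e4),
    )
    def test_monotone_bounded(self, x, dx, km, dk, v):
        """Increasing in x and V, decreasing in Km, bounded above by V
        (up to round-off)."""
        eps = 1e-12 * v
        base = saturation_term(x, km, v)
        assert base < v or x == 0
        assert saturation_term(x + dx, km, v) >= base - eps
        assert saturation_term(x, km + dk, v) <= base + eps
        assert saturation_term(x, km, v * 2) >= base - eps


class TestAssembleRhs:
    def test_single_saturation_conversion(self):
        m = simple_model(
            [Reaction("r", reactants=(("A", 1),), products=(("B", 1),),
                      rate_law=RateLaw("saturation", V=1.0, Km=1.0,
                                       substrate_ids=("A",)))],
            [("A", 1.0, False), ("B", 0.0, False)],
        )
        d = assemble_rhs(m)({"A": 1.0, "B": 0.0})
        assert d["A"] == pytest.approx(-0.5)
        assert d["B"] == pytest.approx(0.5)

    def test_boundary_species_clamped(self, fed_chain):
        d = assemble_rhs(fed_chain)({"Src": 4.0, "A": 0.3, "Snk": 0.0})
        assert d["Src"] == 0.0
        assert d["Snk"] == 0.0

    def test_glucose_block_derivative_is_sum_of_printed_terms(self):
        """At the hypoglycaemic state the glucose derivative equals the
        hand-evaluated signed sum of the seven rate terms."""
        m = apply_scenario(
            build_fixture("glucose_block"), builtin_scenario("hypoglycaemic")
        )
        state = m.initial_state()
        assert state["Glucose"] == 400.0
        # hand evaluation, term by term
        expected = (
            state["LimitDextrin"] / (KM["limit_dextrin"] + state["LimitDextrin"])
            + state["Sucrose"] / (KM["sucrose"] + state["Sucrose"])
            + state["Trehalose"] / (KM["trehalose"] + state["Trehalose"])
            + state["Lactose"]
            + state["Lactose"] * state["NADH"]
            + state["G6P"] / (KM["g6p"] + state["G6P"])
            - state["Glucose"] / (KM["glucose"] + state["Glucose"])
        )
        d = assemble_rhs(m)(state)
        assert d["Glucose"] == pytest.approx(expected, rel=1e-12)


class TestTimeCourse:
    def test_closed_total_is_constant(self, ab_closed):
        traj = simulate_time_course(ab_closed, t_end=5.0, n_points=101)
        total = traj.concentrations["A"] + traj.concentrations["B"]
        assert np.allclose(total, 4.0, rtol=1e-7)

    def test_grid_and_flux_recompute(self, fed_chain):
        traj = simulate_time_course(fed_chain, t_end=10.0, n_points=51)
        assert len(traj.times) == 51
        assert np.all(np.diff(traj.times) > 0)
        # flux recomputable from concentrations via the rate laws
        a = traj.concentrations["A"].to_numpy()
        assert np.allclose(traj.fluxes["out"], a / (0.7 + a), rtol=1e-12)

    def test_concentrations_stay_nonnegative(self):
        traj = simulate_time_course(build_fixture("beta_oxidation"), 100.0, 201)
        assert (traj.concentrations.to_numpy() >= -1e-9).all()

    def test_scoa_dips_then_recovers(self):
        """Succinyl-CoA falls at first (drain exceeds supply) and recovers
        as alpha-ketoglutarate builds up."""
        traj = simulate_time_course(build_fixture("tca_dldd"), 400.0, 401)
        scoa = traj.concentrations["SCoA"].to_numpy()
        imin = int(scoa.argmin())
        assert scoa[imin] < scoa[0]
        assert 0 < imin < len(scoa) - 1
        assert scoa[-1] > scoa[imin]

    def test_uremia_nadh_up_nad_down(self):
        m = apply_scenario(build_fixture("beta_oxidation"), builtin_scenario("uremia"))
        traj = simulate_time_course(m, 50.0, 101)
        assert traj.net_change("NADH") > 0
        assert traj.net_change("NAD") < 0

    def test_tolerance_refinement_stable(self, fed_chain):
        """Halving the solver tolerances moves final concentrations < 0.1%."""
        t1 = simulate_time_course(fed_chain, 10.0, 11, rtol=1e-8, atol=1e-12)
        t2 = simulate_time_course(fed_chain, 10.0, 11, rtol=5e-9, atol=5e-13)
        a1, a2 = t1.final("A"), t2.final("A")
        assert abs(a1 - a2) / a1 < 1e-3

    def test_conservation_along_trajectory(self):
        """Every conservation vector stays constant along a closed fixture's
        trajectory to integration tolerance."""
        m = build_fixture("phosphagen")
        N = stoichiometric_matrix(m)
        rels = conservation_relations(N)
        traj = simulate_time_course(m, 2.0, 101)
        for rel in rels:
            series = sum(
                w * traj.concentrations[s] for s, w in rel.items() if w
            )
            assert np.allclose(series, series.iloc[0], rtol=1e-7)


class TestSteadyState:
    def test_fed_chain_matches_bisection_oracle(self, fed_chain):
        """Steady A solves inflow = A/(Km+A); oracle: scalar bisection."""
        inflow = 4.0 / (2.0 + 4.0)
        oracle = bisect(lambda a: a / (0.7 + a) - inflow, 1e-12, 1e6, xtol=1e-12)
        ss = find_steady_state(fed_chain)
        assert ss.concentrations["A"] == pytest.approx(oracle, rel=1e-8)
        assert ss.residual < 1e-9

    def test_symmetric_exchange_equalizes(self, ab_closed):
        ss = find_steady_state(ab_closed)
        assert ss.concentrations["A"] == pytest.approx(ss.concentrations["B"], rel=1e-6)

    def test_core_energy_flux_balance(self):
        ss = find_steady_state(build_fixture("core_energy"))
        vmax = max(abs(v) for v in ss.fluxes.values())
        assert ss.nv_residual < 1e-8 * vmax

    def test_all_fixtures_reach_tolerance(self):
        for name in ("glucose_block", "core_energy", "phosphagen",
                     "tca_dldd", "beta_oxidation"):
            ss = find_steady_state(build_fixture(name))
            assert ss.residual < 1e-9, name

    def test_nonconvergence_raises_with_residual(self):
        # constant inflow with no drain can never balance
        m = simple_model(
            [Reaction("in", reactants=(("Src", 1),), products=(("A", 1),),
                      rate_law=RateLaw("constant", V=1.0))],
            [("Src", 1.0, True), ("A", 0.0, False)],
        )
        with pytest.raises(ConvergenceError) as err:
            find_steady_state(m, max_horizon=1e3)
        assert err.value.residual > 0
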