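"""Scenario application, the AKGDHC inhibition scan and trajectory readouts."""

import numpy as np
import pandas as pd
import pytest

from kinemet.core import ModelError
from kinemet.engine import Trajectory, find_steady_state, simulate_time_course
from kinemet.fixtures import build_fixture
from kinemet.scenarios import (
    DEFAULT_DLDD_FRACTIONS,
    Scenario,
    apply_scenario,
    builtin_scenario,
    dldd_inhibition_scan,
    load_scenario_config,
    scenario_readouts,
)
from kinemet.sbml import write_sbml


class TestApplyScenario:
    def test_hypoglycaemic_clamps_glucose(self):
        m = apply_scenario(build_fixture("glucose_block"),
                           builtin_scenario("hypoglycaemic"))
        assert m.species_by_id("Glucose").initial_concentration == 400.0

    def test_hyperglycaemic_clamps_glucose(self):
        m = apply_scenario(build_fixture("glucose_block"),
                           builtin_scenario("hyperglycaemic"))
        assert m.species_by_id("Glucose").initial_concentration == 11100.0

    def test_normal_is_identity(self):
        base = build_fixture("tca_dldd")
        out = apply_scenario(base, builtin_scenario("normal"))
        assert write_sbml(out) == write_sbml(base)

    def test_application_is_pure(self):
        base = build_fixture("beta_oxidation")
        before = write_sbml(base)
        apply_scenario(base, builtin_scenario("uremia"))
        assert write_sbml(base) == before

    def test_unknown_override_rejected(self):
        scen = Scenario("bogus", initial_overrides={"Unobtainium": 1.0})
        with pytest.raises(ModelError, match="Unobtainium"):
            apply_scenario(build_fixture("phosphagen"), scen)

    def test_v_scaling_multiplies(self):
        scen = Scenario("half", v_scalings={"RE103": 0.5})
        m = build_fixture("tca_dldd")
        out = apply_scenario(m, scen)
        assert out.reaction_by_id("RE103").rate_law.V == pytest.approx(
            0.5 * m.reaction_by_id("RE103").rate_law.V
        )


@pytest.fixture(scope="module")
def scan():
    return dldd_inhibition_scan(build_fixture("tca_dldd"))


@pytest.fixture(scope="module")
def trajectories():
    base = build_fixture("beta_oxidation")
    out = {}
    for name in ("normal", "uremia"):
        m = apply_scenario(base, builtin_scenario(name))
        out[name] = simulate_time_course(m, 50.0, 101)
    return out


class TestDlddScan:
    def test_baseline_matches_unmodified_steady_state(self):
        m = build_fixture("tca_dldd")
        scan = dldd_inhibition_scan(m, fractions=[0.0])
        base = scan.scanned_flux[0]
        # reference: relax then polish, same protocol as the scan
        relaxed = simulate_time_course(m, 5000.0, 2)
        guess = {s: float(relaxed.concentrations[s].iloc[-1]) for s in m.species_ids}
        ss = find_steady_state(m, initial=guess)
        assert base == pytest.approx(ss.fluxes["RE103"], rel=1e-6)

    def test_fraction_grid_includes_baseline(self, scan):
        assert scan.fractions[0] == 0.0
        assert set(DEFAULT_DLDD_FRACTIONS) <= set(scan.fractions)

    def test_scanned_flux_non_increasing(self, scan):
        flux = scan.scanned_flux
        assert all(v is not None for v in flux)
        assert all(a >= b - 1e-12 for a, b in zip(flux, flux[1:]))
        # drastic drop by 95 % inhibition
        assert flux[-1] < 0.5 * flux[0]

    def test_pyruvate_non_decreasing(self, scan):
        pyr = scan.pyruvate
        assert all(a <= b + 1e-12 for a, b in zip(pyr, pyr[1:]))

    def test_atp_generation_falls(self, scan):
        assert scan.atp_generation[-1] < scan.atp_generation[0]

    def test_rejects_bad_fractions(self):
        with pytest.raises(ValueError):
            dldd_inhibition_scan(build_fixture("tca_dldd"), fractions=[1.5])

    def test_unknown_reaction(self):
        with pytest.raises(KeyError):
            dldd_inhibition_scan(build_fixture("tca_dldd"), reaction="REnope")


class TestReadouts:
    def test_uremic_lcac_ratio_exceeds_normal(self, trajectories):
        normal = scenario_readouts(trajectories["normal"])["lcac_carnitine_ratio"]
        uremic = scenario_readouts(trajectories["uremia"])["lcac_carnitine_ratio"]
        assert uremic > normal

    def test_c22_substrate_product_anticorrelated(self, trajectories):
        r = scenario_readouts(trajectories["uremia"])["c22_correlation"]
        assert r < 0

    def test_nadh_up_nad_down_under_uremia(self, trajectories):
        r = scenario_readouts(trajectories["uremia"])
        assert r["nadh_net_change"] > 0
        assert r["nad_net_change"] < 0

    def test_missing_species_marked_unavailable(self, trajectories):
        r = scenario_readouts(trajectories["normal"])
        assert r["atp_net_change"] == "unavailable"  # no ATP in this fixture

    def test_constant_trajectory_zero_net_change(self):
        times = np.linspace(0, 1, 5)
        conc = pd.DataFrame({"NADH": [2.0] * 5, "NAD": [3.0] * 5})
        flux = pd.DataFrame(index=range(5))
        traj = Trajectory(times=times, concentrations=conc, fluxes=flux)
        r = scenario_readouts(traj, readouts=("nadh_net_change", "nad_net_change"))
        assert r["nadh_net_change"] == 0.0
        assert r["nad_net_change"] == 0.0


class TestConfig:
    def test_key_value_config_parses(self):
        text = """
        # uremic override set
        name: uremia-custom
        override.C22AcylCoA: 15
        override.Carnitine: 2
        scale.RE201: 0.2
        focal: Glucose
        readout: lcac_carnitine_ratio
        readout: c22_correlation
        """
        scen = load_scenario_config(text)
        assert scen.name == "uremia-custom"
        assert scen.initial_overrides == {"C22AcylCoA": 15.0, "Carnitine": 2.0}
        assert scen.v_scalings == {"RE201": 0.2}
        assert scen.focal == "Glucose"
        assert scen.readouts == ("lcac_carnitine_ratio", "c22_correlation")

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown key"):
            load_scenario_config("bogus: 1")
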