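"""Plant-model unit and property tests: RHS arithmetic, steady states,
integration accuracy and state nonnegativity."""

import math

import numpy as np
import pytest
from scipy import optimize

from aersim.process_model import (
    ProcessParams,
    ProcessState,
    SimulationDiverged,
    derivatives,
    simulate,
    steady_state,
)


class TestDerivatives:
    def test_no_biomass_fresh_influent_leaves_only_aeration(self, oracle_params):
        # X=0 and S=s_in kill every consumption term; O=0 maximizes transfer
        state = ProcessState(O=0.0, S=400.0, X=0.0)
        dO, dS, dX = derivatives(state, oracle_params, airflow=40.0)
        assert dO == pytest.approx(0.25 * 40.0 * 9.08)
        assert dS == 0.0
        assert dX == 0.0

    def test_zero_substrate_dilution_and_decay_only(self, oracle_params):
        state = ProcessState(O=2.0, S=0.0, X=1000.0)
        dO, dS, dX = derivatives(state, oracle_params, airflow=50.0)
        assert dS == pytest.approx(0.125 * 400.0)
        assert dX == pytest.approx(-0.0025 * 1000.0)

    def test_matches_frozen_hand_evaluation(self, oracle_params, mid_state):
        # frozen independent arithmetic evaluation of the three balances at
        # O=2, S=100, X=2600, airflow=50 with the round-number parameters
        dO, dS, dX = derivatives(mid_state, oracle_params, airflow=50.0)
        assert dO == pytest.approx(52.825, abs=1e-12)
        assert dS == pytest.approx(-287.5, abs=1e-12)
        assert dX == pytest.approx(188.5, abs=1e-12)

    @pytest.mark.parametrize("airflow", [-1.0, 101.0, math.nan])
    def test_out_of_bounds_airflow_rejected(self, oracle_params, mid_state, airflow):
        with pytest.raises(ValueError):
            derivatives(mid_state, oracle_params, airflow)

    def test_non_finite_state_rejected(self):
        with pytest.raises(ValueError):
            ProcessState(O=math.inf, S=1.0, X=1.0)


class TestSteadyState:
    def test_substrate_matches_closed_form(self, default_params):
        res = steady_state(default_params, airflow=50.0)
        assert res.found
        expected = default_params.substrate_steady_state()
        assert res.state.S == pytest.approx(expected, rel=1e-6)
        assert res.residual < 1e-8

    def test_closed_form_value(self, default_params):
        # S* = K_d K_s / (eta K - K_d) with the default kinetics
        assert default_params.substrate_steady_state() == pytest.approx(
            0.0025 * 60.0 / (0.6 * 5.0 / 24.0 - 0.0025), rel=1e-12
        )

    def test_zero_airflow_has_no_oxygenated_steady_state(self, default_params):
        res = steady_state(default_params, airflow=0.0)
        assert (not res.found) or res.state.O == pytest.approx(0.0, abs=1e-6)

    def test_airflow_out_of_bounds_rejected(self, default_params):
        with pytest.raises(ValueError):
            steady_state(default_params, airflow=-5.0)


def constant_airflow(level):
    return lambda y_ref, y, t: level


class TestSimulate:
    def test_zero_horizon_returns_initial_state_only(self, default_params, mid_state):
        traj = simulate(mid_state, default_params, constant_airflow(50.0), 2.0, horizon=0.0)
        assert len(traj) == 1
        assert traj.final_state.O == mid_state.O

    def test_relaxes_to_root_found_steady_state(self, default_params):
        ss = steady_state(default_params, airflow=50.0).state
        start = ProcessState(O=1.0, S=ss.S * 1.2, X=ss.X)
        traj = simulate(start, default_params, constant_airflow(50.0), 2.0, horizon=48.0)
        assert traj.final_state.O == pytest.approx(ss.O, abs=1e-3)
        assert traj.final_state.S == pytest.approx(ss.S, abs=1e-3)

    def test_dilution_only_follows_exponential_closed_form(self, default_params):
        # with X=0 the substrate balance is linear: S(t) relaxes to s_in at rate lam
        s0 = 100.0
        start = ProcessState(O=2.0, S=s0, X=0.0)
        traj = simulate(start, default_params, constant_airflow(50.0), 2.0, horizon=8.0)
        p = default_params
        expected = p.s_in + (s0 - p.s_in) * np.exp(-p.lam * traj.t)
        assert np.allclose(traj.S, expected, rtol=1e-6)

    def test_no_aeration_oxygen_monotonically_depletes(self, default_params):
        start = ProcessState(O=5.0, S=default_params.s_in, X=0.0)
        # S pinned at s_in and X=0: only the substrate-deficit sink is absent,
        # transfer term is zero at airflow 0, so O cannot increase
        traj = simulate(start, default_params, constant_airflow(0.0), 2.0, horizon=2.0)
        assert np.all(np.diff(traj.O) <= 1e-12)

    def test_rk4_grid_convergence(self, default_params):
        start = ProcessState(O=1.0, S=50.0, X=3000.0)
        ends = []
        for dt in (0.01, 0.005):
            traj = simulate(start, default_params, constant_airflow(60.0), 2.0,
                            horizon=4.0, dt=dt)
            ends.append(traj.final_state.as_array())
        assert np.max(np.abs(ends[0] - ends[1])) < 1e-4

    def test_negative_excursions_clipped_and_counted(self, default_params):
        start = ProcessState(O=0.05, S=1.0, X=12000.0)
        traj = simulate(start, default_params, constant_airflow(0.0), 2.0, horizon=1.0)
        assert traj.O.min() >= 0.0
        assert traj.S.min() >= 0.0
        assert traj.clip_events > 0

    def test_out_of_range_controller_command_is_clipped(self, default_params, mid_state):
        traj = simulate(mid_state, default_params, constant_airflow(1e9), 2.0, horizon=0.5)
        assert np.all(traj.airflow <= default_params.mu_max)

    def test_divergence_aborts_with_diagnostic(self, oracle_params):
        # near-unit yield, huge saturated substrate and negligible decay make
        # biomass grow exponentially at ~5/h until the guard trips
        runaway = ProcessParams(
            eta=1.0, k_resp=0.005, k_max=5.0, k_s=60.0, lam=10.0, k_d=1e-6,
            s_in=9e5, o_sat=9.08, k_air=0.25, mu_max=100.0,
        )
        start = ProcessState(O=2.0, S=9e5 * 0.9, X=10.0)
        with pytest.raises(SimulationDiverged):
            simulate(start, runaway, constant_airflow(50.0), 2.0, horizon=50.0, dt=0.2)

    def test_disturbance_changes_named_parameter(self, default_params):
        ss = steady_state(default_params, airflow=50.0).state
        traj = simulate(ss, default_params, constant_airflow(50.0), 2.0, horizon=4.0,
                        disturbances=[(1.0, "s_in", default_params.s_in * 2)])
        # doubled influent load drags DO down after t=1
        assert traj.O[-1] < ss.O - 0.5

    def test_unknown_disturbance_parameter_rejected(self, default_params, mid_state):
        with pytest.raises(ValueError):
            simulate(mid_state, default_params, constant_airflow(50.0), 2.0,
                     horizon=1.0, disturbances=[(0.5, "bogus", 1.0)])


def test_default_k_air_sized_for_design_point():
    # by construction airflow 50 m^3/h holds DO = 2 mg/L at the biological steady state
    p = ProcessParams.default()
    ss = steady_state(p, airflow=50.0)
    assert ss.found
    assert ss.state.O == pytest.approx(2.0, abs=1e-9)


def test_trajectory_frame_has_canonical_columns(default_params, mid_state):
    traj = simulate(mid_state, default_params, constant_airflow(50.0), 2.0, horizon=0.1)
    df = traj.to_frame()
    assert list(df.columns) == [
        "t_h", "O_mgL", "S_mgL", "X_mgL", "airflow_m3h", "setpoint_mgL",
    ]
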