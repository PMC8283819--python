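"""Fuzzy-controller tests: quantization arithmetic, membership partition,
inference against a brute-force rule loop, symmetry/monotonicity of the
closed map, and the adaptive center refinement."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from aersim.fuzzy_controller import (
    ActuatorMap,
    FuzzyController,
    LoopSignals,
    RuleBase,
    TERMS,
    TuningScenario,
    compute_quantization,
    control_step,
    defuzzify,
    fuzzify,
    infer,
    quantize,
    tune_fnn,
)
from aersim.process_model import ProcessParams, ProcessState, steady_state


SPEC = compute_quantization(n=6, e_max=2.0, ec_max=1.5, u_max=1.0)
RB = RuleBase()


def brute_force_infer(mu_e, mu_ec, rulebase):
    """Independent oracle: explicit loop over all 49 rules."""
    weights = [0.0] * len(TERMS)
    table = rulebase.table
    for a in range(7):
        for b in range(7):
            weights[table[a][b]] += mu_e[a] * mu_ec[b]
    return np.array(weights)


class TestQuantization:
    def test_error_factor_from_stated_universes(self):
        # n=6 over e in [-2, +2] gives K_e = 3
        assert SPEC.K_e == 3.0

    def test_output_factor_is_one_sixth(self):
        assert SPEC.K_u == pytest.approx(1.0 / 6.0)

    def test_error_change_factor_follows_definition(self):
        # n/ec_max = 6/1.5; the legacy rounded value 3 stays available as an override
        assert SPEC.K_ec == 4.0
        assert compute_quantization(6, 2.0, 1.5, 1.0, kec_override=3.0).K_ec == 3.0

    @pytest.mark.parametrize("bad", [{"e_max": -1.0}, {"ec_max": 0.0}, {"u_max": -2.0}])
    def test_nonpositive_halfwidth_rejected(self, bad):
        kwargs = {"n": 6, "e_max": 2.0, "ec_max": 1.5, "u_max": 1.0, **bad}
        with pytest.raises(ValueError):
            compute_quantization(**kwargs)

    @pytest.mark.parametrize(
        "value,factor,n,expected",
        [
            (0.0, 3.0, 6, 0),
            (2.0, 3.0, 6, 6),      # boundary maps to boundary, no clipping
            (0.5, 3.0, 6, 2),      # tie 1.5 rounds away from zero
            (-0.5, 3.0, 6, -2),
            (5.0, 3.0, 6, 6),      # beyond the universe clips
            (-5.0, 3.0, 6, -6),
        ],
    )
    def test_quantize_examples(self, value, factor, n, expected):
        assert quantize(value, factor, n) == expected

    def test_quantize_rejects_non_finite(self):
        with pytest.raises(ValueError):
            quantize(math.nan, 3.0, 6)

    @given(st.floats(-10, 10))
    def test_quantize_always_lands_in_universe(self, value):
        assert -6 <= quantize(value, 3.0, 6) <= 6


class TestMembership:
    @pytest.mark.parametrize("center_idx", range(7))
    def test_term_center_is_crisp(self, center_idx):
        mu = fuzzify(RB.centers[center_idx], RB)
        assert mu[center_idx] == 1.0
        assert mu.sum() == 1.0

    def test_midpoint_splits_evenly(self):
        mu = fuzzify(1.0, RB)  # halfway between ZO (0) and PS (2)
        assert mu[TERMS.index("ZO")] == pytest.approx(0.5)
        assert mu[TERMS.index("PS")] == pytest.approx(0.5)

    @given(st.floats(-6, 6, allow_nan=False))
    def test_partition_of_unity(self, value):
        mu = fuzzify(value, RB)
        assert mu.sum() == pytest.approx(1.0, abs=1e-12)
        assert (mu >= 0).all()
        assert np.count_nonzero(mu) <= 2

    def test_out_of_range_input_clipped(self):
        mu = fuzzify(9.0, RB)
        assert mu[-1] == 1.0


class TestInference:
    def test_zero_inputs_put_all_weight_on_zero_term(self):
        w = infer(fuzzify(0, RB), fuzzify(0, RB), RB)
        assert w[TERMS.index("ZO")] == pytest.approx(1.0)

    def test_single_active_rule(self):
        mu_e = np.zeros(7); mu_e[6] = 1.0   # PB error
        mu_ec = np.zeros(7); mu_ec[3] = 1.0  # ZO change
        w = infer(mu_e, mu_ec, RB)
        out = RB.table[6][3]
        assert w[out] == pytest.approx(1.0)

    @given(st.floats(-6, 6), st.floats(-6, 6))
    def test_matches_brute_force_loop(self, e_val, ec_val):
        mu_e, mu_ec = fuzzify(e_val, RB), fuzzify(ec_val, RB)
        assert np.allclose(
            infer(mu_e, mu_ec, RB), brute_force_infer(mu_e, mu_ec, RB), atol=1e-12
        )

    def test_weights_sum_to_one(self):
        w = infer(fuzzify(1.3, RB), fuzzify(-0.7, RB), RB)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_rule_table_antisymmetric(self):
        tab = RB.table_array - 3  # signed term indices
        assert np.array_equal(tab, -tab[::-1, ::-1])


class TestDefuzzify:
    def test_all_weight_on_zero_term(self):
        w = np.zeros(7); w[3] = 1.0
        assert defuzzify(w, RB, SPEC.K_u) == 0.0

    def test_all_weight_on_positive_big(self):
        w = np.zeros(7); w[6] = 1.0
        assert defuzzify(w, RB, 1.0 / 6.0) == pytest.approx(1.0)

    def test_mixed_weights_match_weighted_mean(self):
        w = np.array([0.0, 0.0, 0.25, 0.5, 0.25, 0.0, 0.0])
        # frozen arithmetic: (1/6) * (0.25*(-2) + 0.5*0 + 0.25*2) = 0
        assert defuzzify(w, RB, 1.0 / 6.0) == pytest.approx(0.0)
        w2 = np.array([0.0, 0.0, 0.0, 0.5, 0.3, 0.2, 0.0])
        # (1/6) * (0.3*2 + 0.2*4) = 1.4/6
        assert defuzzify(w2, RB, 1.0 / 6.0) == pytest.approx(1.4 / 6.0)

    def test_degenerate_zero_weights_give_zero(self):
        assert defuzzify(np.zeros(7), RB, SPEC.K_u) == 0.0


def _signals(e_prev):
    return LoopSignals(y_ref=2.0, y=2.0 - e_prev, e=e_prev, ec=0.0, E=0, Ec=0, u=0.0)


class TestControlStep:
    def test_on_setpoint_two_steps_gives_zero(self):
        u1, s1 = control_step(2.0, 2.0, None, SPEC, RB)
        u2, _ = control_step(2.0, 2.0, s1, SPEC, RB)
        assert u1 == 0.0 and u2 == 0.0

    def test_saturated_error_demands_full_output(self):
        # y far below setpoint: e at +e_max with ec = 0
        u, sig = control_step(2.0, 0.0, _signals(2.0), SPEC, RB)
        assert u == pytest.approx(SPEC.u_max)
        assert sig.E == 6 and sig.Ec == 0

    @given(st.floats(-2, 2), st.floats(-1.5, 1.5))
    def test_pipeline_matches_composed_brute_force(self, e, ec):
        prev = _signals(e - ec)
        u, _ = control_step(2.0, 2.0 - e, prev, SPEC, RB)
        E = quantize(e, SPEC.K_e, SPEC.n)
        Ec = quantize(ec, SPEC.K_ec, SPEC.n)
        w = brute_force_infer(fuzzify(E, RB), fuzzify(Ec, RB), RB)
        expected = defuzzify(w, RB, SPEC.K_u)
        assert u == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-2, 2), st.floats(-1.5, 1.5))
    def test_antisymmetric_response(self, e, ec):
        u_pos, _ = control_step(2.0, 2.0 - e, _signals(e - ec), SPEC, RB)
        u_neg, _ = control_step(2.0, 2.0 + e, _signals(-(e - ec)), SPEC, RB)
        assert u_pos == pytest.approx(-u_neg, abs=1e-12)

    def test_monotone_in_error_at_zero_change(self):
        es = np.linspace(-2.0, 2.0, 201)
        us = [control_step(2.0, 2.0 - e, _signals(e), SPEC, RB)[0] for e in es]
        assert np.all(np.diff(us) >= -1e-12)

    @given(st.floats(-5, 5), st.floats(-5, 5))
    def test_output_bounded(self, e, ec):
        u, _ = control_step(2.0, 2.0 - e, _signals(e - ec), SPEC, RB)
        assert abs(u) <= SPEC.u_max + 1e-12


class TestActuatorMap:
    def test_affine_map_and_clipping(self):
        act = ActuatorMap(bias=50.0, span=20.0, mu_max=100.0, trim_gain=0.0)
        assert act(0.0, 0.0, 0.02) == 50.0
        assert act(1.0, 0.0, 0.02) == 70.0
        assert act(-1.0, 0.0, 0.02) == 30.0
        act_sat = ActuatorMap(bias=95.0, span=20.0, mu_max=100.0, trim_gain=0.0)
        assert act_sat(1.0, 0.0, 0.02) == 100.0

    def test_integral_trim_accumulates_and_clamps(self):
        act = ActuatorMap(bias=50.0, span=20.0, trim_gain=10.0, trim_limit=5.0)
        for _ in range(200):
            act(0.0, 1.0, 0.02)
        assert act.trim == pytest.approx(5.0)

    def test_controller_command_always_within_actuator_range(self):
        ctrl = FuzzyController.default()
        ctrl.reset()
        rng = np.random.default_rng(7)
        for y in rng.uniform(0.0, 9.0, size=200):
            cmd = ctrl(2.0, float(y), 0.0)
            assert 0.0 <= cmd <= 100.0


@pytest.fixture(scope="module")
def tuning_scenario():
    params = ProcessParams.default()
    ss = steady_state(params, airflow=50.0).state
    initial = ProcessState(O=0.5, S=ss.S, X=ss.X)
    return TuningScenario(initial=initial, params=params, horizon=2.0)


class TestAdaptiveTuning:
    def test_zero_learning_rate_is_identity(self, tuning_scenario):
        tuned, report = tune_fnn(RB, tuning_scenario, episodes=1, learning_rate=0.0, seed=1)
        assert tuned is RB
        assert report["improved"] is False

    def test_cost_never_worsens(self, tuning_scenario):
        tuned, report = tune_fnn(RB, tuning_scenario, episodes=1, learning_rate=0.5, seed=1)
        hist = report["cost_history"]
        assert hist[-1] <= hist[0]

    def test_detuned_zero_center_is_recovered(self, tuning_scenario):
        # shifting every output center +1 biases the zero-error action, which
        # leaves a steady offset; tuning must pull the ZO center back to 0
        shifted = tuple(float(np.clip(c + 1.0, -6, 6)) for c in RB.centers)
        detuned = RuleBase(output_centers=shifted)
        tuned, report = tune_fnn(
            detuned, tuning_scenario, episodes=3, learning_rate=1.0, seed=3
        )
        assert report["improved"]
        assert report["cost_history"][-1] < report["cost_history"][0]
        zo = TERMS.index("ZO")
        assert abs(tuned.output_centers[zo]) < abs(detuned.output_centers[zo])
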