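"""Learning rules, probability weighting, choice rule and whole-session
evaluation, checked against hand-derived values and a naive oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stressrl import (
    AgentParams,
    MODEL_NAMES,
    ParameterError,
    TaskConfig,
    choice_probability,
    run_model,
    simulate_agent,
    update_asymmetric,
    update_pearce_hall,
    update_split_half,
    update_static,
    weight_probability,
)
from stressrl.models import log_likelihood_fast, trials_to_arrays

from .conftest import random_params
from .oracles import naive_log_likelihood


class TestUpdateRules:
    def test_static_rescorla_wagner(self):
        assert update_static(0.5, 1, 0.1) == pytest.approx((0.55, 0.5))
        assert update_static(0.5, 0, 0.1) == pytest.approx((0.45, -0.5))

    def test_static_zero_prediction_error(self):
        new_p, delta = update_static(1.0, 1, 0.3)
        assert (new_p, delta) == (1.0, 0.0)

    def test_static_rejects_bad_rate(self):
        with pytest.raises(ParameterError):
            update_static(0.5, 1, 1.5)

    def test_asymmetric_rates(self):
        assert update_asymmetric(0.5, 1, 0.2, 0.05) == pytest.approx((0.60, 0.5))
        assert update_asymmetric(0.5, 0, 0.2, 0.05) == pytest.approx((0.475, -0.5))

    def test_asymmetric_equal_rates_reduce_to_static(self):
        for p, r in [(0.3, 1), (0.8, 0), (0.5, 1)]:
            assert update_asymmetric(p, r, 0.15, 0.15) == update_static(p, r, 0.15)

    def test_pearce_hall_hand_example(self):
        # delta = 0.5, S' = 0.5*1 + 0.5*0.5 = 0.75, alpha = 0.4*0.75 = 0.3,
        # p' = 0.5 + 0.3*0.5 = 0.65
        new_p, new_s, alpha_t, delta = update_pearce_hall(0.5, 1, 1.0, 0.5, 0.4)
        assert (new_p, new_s, alpha_t, delta) == pytest.approx((0.65, 0.75, 0.3, 0.5))

    def test_pearce_hall_mu_to_zero_keeps_associability(self):
        _, new_s, alpha_t, _ = update_pearce_hall(0.5, 1, 1.0, 1e-12, 0.4)
        assert new_s == pytest.approx(1.0)
        assert alpha_t == pytest.approx(0.4)

    def test_pearce_hall_associability_converges_to_constant_delta(self):
        # iterating with |delta| held at c drives S to the fixed point c
        s = 1.0
        c = 0.3
        for _ in range(200):
            s = (1 - 0.5) * s + 0.5 * c
        assert s == pytest.approx(c, abs=1e-10)

    def test_pearce_hall_rate_clamped(self):
        _, _, alpha_t, _ = update_pearce_hall(0.0, 1, 3.0, 0.5, 0.9)
        assert alpha_t == 1.0

    def test_pearce_hall_rejects_negative_associability(self):
        with pytest.raises(ParameterError):
            update_pearce_hall(0.5, 1, -0.1, 0.5, 0.4)

    def test_split_half_boundary(self):
        # trial 30 of 60 uses the first rate, trial 31 the second
        assert update_split_half(0.5, 1, 30, 60, 0.1, 0.3) == pytest.approx((0.55, 0.5))
        assert update_split_half(0.5, 1, 31, 60, 0.1, 0.3) == pytest.approx((0.65, 0.5))
        assert update_split_half(0.5, 1, 40, 60, 0.1, 0.3) == pytest.approx((0.65, 0.5))

    def test_split_half_index_validation(self):
        from stressrl import InputError

        with pytest.raises(InputError):
            update_split_half(0.5, 1, 61, 60, 0.1, 0.3)


class TestProbabilityWeighting:
    def test_identity_at_gamma_one(self):
        for p in np.linspace(0, 1, 101):
            assert weight_probability(p, 1.0) == pytest.approx(p, abs=1e-15)

    def test_half_is_fixed_point(self):
        for gamma in (0.1, 1.0, 5.0, 100.0):
            assert weight_probability(0.5, gamma) == 0.5

    def test_clipping(self):
        assert weight_probability(0.25, 2.0) == 0.0
        assert weight_probability(0.9, 2.0) == 1.0

    def test_rejects_nonpositive_gamma(self):
        with pytest.raises(ParameterError):
            weight_probability(0.5, 0.0)

    @given(
        p=st.floats(0, 1),
        gamma=st.floats(1e-6, 1e6, allow_nan=False, allow_infinity=False),
    )
    @settings(max_examples=200, derandomize=True)
    def test_bounded_and_complementary(self, p, gamma):
        f = weight_probability(p, gamma)
        assert 0.0 <= f <= 1.0
        assert weight_probability(1 - p, gamma) == pytest.approx(1 - f, abs=1e-12)


class TestChoiceRule:
    def test_indifference(self):
        assert choice_probability(50, 50, 0.3) == 0.5
        assert choice_probability(10, 90, 0.0) == 0.5

    def test_sigmoid_value(self):
        assert choice_probability(60, 40, 0.05) == pytest.approx(
            1 / (1 + math.exp(-1)), rel=1e-12
        )

    def test_symmetry(self):
        p = choice_probability(70, 20, 0.1)
        assert choice_probability(20, 70, 0.1) == pytest.approx(1 - p, abs=1e-15)

    def test_overflow_safe(self):
        assert choice_probability(100, 0, 1e6) == pytest.approx(1.0)
        assert choice_probability(0, 100, 1e6) == pytest.approx(0.0)


class TestRunModel:
    def test_random_agent_likelihood(self, s1w_trials):
        params = AgentParams("s1", alpha=0.1, beta=0.0)
        _, ll = run_model(params, s1w_trials)
        assert ll == pytest.approx(60 * math.log(0.5), rel=1e-12)

    def test_gamma_one_matches_base_model(self, s1w_trials):
        base = AgentParams("s1", alpha=0.17, beta=0.08)
        weighted = AgentParams("s1w", alpha=0.17, gamma=1.0, beta=0.08)
        _, ll_base = run_model(base, s1w_trials)
        _, ll_w = run_model(weighted, s1w_trials)
        assert ll_w == pytest.approx(ll_base, abs=1e-10)

    @pytest.mark.parametrize(
        "nested, full",
        [
            (AgentParams("s1", alpha=0.2, beta=0.1),
             AgentParams("s2", alpha_pos=0.2, alpha_neg=0.2, beta=0.1)),
            (AgentParams("s1", alpha=0.2, beta=0.1),
             AgentParams("d2", alpha1=0.2, alpha2=0.2, beta=0.1)),
            (AgentParams("s2w", alpha_pos=0.3, alpha_neg=0.1, beta=0.05, gamma=1.0),
             AgentParams("s2", alpha_pos=0.3, alpha_neg=0.1, beta=0.05)),
            (AgentParams("d1w", mu=0.4, kappa=0.3, beta=0.05, gamma=1.0),
             AgentParams("d1", mu=0.4, kappa=0.3, beta=0.05)),
            (AgentParams("d2w", alpha1=0.3, alpha2=0.1, beta=0.05, gamma=1.0),
             AgentParams("d2", alpha1=0.3, alpha2=0.1, beta=0.05)),
        ],
    )
    def test_model_nesting(self, nested, full, s1w_trials):
        _, ll_a = run_model(nested, s1w_trials)
        _, ll_b = run_model(full, s1w_trials)
        assert ll_a == pytest.approx(ll_b, abs=1e-10)

    def test_empty_trials_rejected(self):
        from stressrl import InputError

        with pytest.raises(InputError):
            run_model(AgentParams("s1", alpha=0.1, beta=0.1), [])

    def test_trace_initialization_and_complementarity(self, s1w_params, s1w_trials):
        trace, _ = run_model(s1w_params, s1w_trials)
        assert trace.p_pred[0] == 0.5
        # block reset: the first trial of each block starts back at 0.5
        for i, rec in enumerate(s1w_trials):
            if rec.trial_index in (21, 41):
                assert trace.p_pred[i] == 0.5
        assert np.all((trace.p_pred >= 0) & (trace.p_pred <= 1))
        assert np.all((trace.p_choice_A > 0) & (trace.p_choice_A < 1))

    @pytest.mark.parametrize("model_name", MODEL_NAMES)
    @pytest.mark.parametrize("reset", [True, False])
    def test_matches_naive_oracle(self, model_name, reset):
        rng = np.random.default_rng(hash(model_name) % 2**31)
        cfg = TaskConfig()
        for _ in range(3):
            params = random_params(model_name, rng)
            trials = simulate_agent(params, cfg, seed=int(rng.integers(2**31)),
                                    reset_at_block=reset)
            _, ll = run_model(params, trials, reset_at_block=reset)
            expected = naive_log_likelihood(params, trials, reset_at_block=reset)
            assert ll == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("model_name", MODEL_NAMES)
    def test_fast_kernel_matches_reference(self, model_name):
        rng = np.random.default_rng(99)
        cfg = TaskConfig()
        for _ in range(3):
            params = random_params(model_name, rng)
            trials = simulate_agent(params, cfg, seed=int(rng.integers(2**31)))
            arrays = trials_to_arrays(trials)
            _, ll = run_model(params, trials)
            assert log_likelihood_fast(params, arrays) == pytest.approx(
                ll, abs=1e-10
            )

    def test_no_response_trials_skipped(self, s1w_params, s1w_trials):
        import copy

        trials = [copy.copy(t) for t in s1w_trials]
        trials[5].chosen = None
        trials[5].response_made = False
        trace, ll = run_model(s1w_params, trials)
        assert np.isnan(trace.delta[5])  # no likelihood term, no update
        assert ll == pytest.approx(naive_log_likelihood(s1w_params, trials), abs=1e-10)
        # the skipped update leaves the next trial's prediction unchanged
        assert trace.p_pred[6] == trace.p_pred[5]


class TestSimulateAgent:
    def test_deterministic_under_seed(self, s1w_params):
        cfg = TaskConfig()
        a = simulate_agent(s1w_params, cfg, seed=5)
        b = simulate_agent(s1w_params, cfg, seed=5)
        assert a == b

    def test_random_agent_near_chance(self):
        from .oracles import naive_correct_proportion

        cfg = TaskConfig()
        params = AgentParams("s1w", alpha=0.3, gamma=1.0, beta=0.0)
        rng = np.random.default_rng(11)
        props = [
            naive_correct_proportion(simulate_agent(params, cfg, rng=rng))
            for _ in range(200)
        ]
        se = np.nanstd(props) / np.sqrt(len(props))
        assert abs(np.nanmean(props) - 0.5) < 3 * se + 0.01

    def test_value_sensitive_agent_above_chance(self):
        from .oracles import naive_correct_proportion

        cfg = TaskConfig()
        params = AgentParams("s1w", alpha=0.3, gamma=1.0, beta=1.0)
        rng = np.random.default_rng(12)
        props = [
            naive_correct_proportion(simulate_agent(params, cfg, rng=rng))
            for _ in range(200)
        ]
        assert np.nanmean(props) > 0.6

    def test_self_consistency_of_likelihood(self):
        # on average, an agent's own parameters explain its behavior better
        # than a perturbed parameter set
        cfg = TaskConfig()
        true = AgentParams("s1w", alpha=0.15, gamma=1.3, beta=0.15)
        off = AgentParams("s1w", alpha=0.45, gamma=0.6, beta=0.03)
        rng = np.random.default_rng(13)
        gaps = []
        for _ in range(100):
            trials = simulate_agent(true, cfg, rng=rng)
            _, ll_true = run_model(true, trials)
            _, ll_off = run_model(off, trials)
            gaps.append(ll_true - ll_off)
        assert np.mean(gaps) > 0
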