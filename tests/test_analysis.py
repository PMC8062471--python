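"""Group analysis: correctness scoring, contrasts, covariate GLMs and the
model-validation regression."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from stressrl import (
    AgentParams,
    AnalysisError,
    CohortSpec,
    TaskConfig,
    TrialRecord,
    generate_cohort,
    group_contrasts,
    parameter_performance_regression,
    performance_table,
    score_correct_choices,
    sex_difference_glm,
    simulate_agent,
    two_way_anova,
    validate_model_regression,
)
from stressrl.cohort import _default_groups
from stressrl.fit import fit_map

from .oracles import naive_correct_proportion

CFG = TaskConfig()


def _trial(idx, mag_a, chosen, high="A", block=1):
    return TrialRecord(
        trial_index=idx,
        block_index=block,
        high_prob_option=high,
        magnitude_A=mag_a,
        magnitude_B=100 - mag_a,
        rewarded="A",
        chosen=chosen,
        response_made=chosen is not None,
    )


class TestScoreCorrectChoices:
    def test_expected_value_rule(self):
        # high option A with magnitude 40: EV 30 vs 15, so A is correct
        rec = score_correct_choices([_trial(1, 40, "A")], CFG)
        assert rec.prop_correct_overall == 1.0
        rec = score_correct_choices([_trial(1, 40, "B")], CFG)
        assert rec.prop_correct_overall == 0.0

    def test_low_probability_option_can_be_correct(self):
        # A high-prob but magnitude 20: EV 15 vs 20, so B is correct
        rec = score_correct_choices([_trial(1, 20, "B")], CFG)
        assert rec.prop_correct_overall == 1.0

    def test_tied_expected_values_excluded(self):
        # magnitudes 25/75 with 0.75/0.25: EV 18.75 both sides
        trials = [_trial(1, 25, "A"), _trial(2, 40, "A")]
        rec = score_correct_choices(trials, CFG)
        assert rec.n_scored == 1
        assert rec.prop_correct_overall == 1.0

    def test_no_response_excluded(self):
        trials = [_trial(1, 40, None), _trial(2, 40, "A")]
        rec = score_correct_choices(trials, CFG)
        assert rec.n_responded == 1 and rec.n_scored == 1

    def test_all_unscorable_flagged(self):
        with pytest.warns(UserWarning):
            rec = score_correct_choices([_trial(1, 40, None)], CFG)
        assert rec.flagged and np.isnan(rec.prop_correct_overall)

    def test_matches_bruteforce_oracle_on_random_logs(self):
        agent = AgentParams("s1w", alpha=0.3, gamma=1.0, beta=0.0)
        rng = np.random.default_rng(17)
        for _ in range(300):
            trials = simulate_agent(agent, CFG, rng=rng)
            mine = score_correct_choices(trials, CFG).prop_correct_overall
            assert mine == naive_correct_proportion(trials)

    def test_block_proportions_reconstruct_overall(self, s1w_trials):
        rec = score_correct_choices(s1w_trials, CFG)
        weighted = sum(
            rec.prop_correct_block[b] * rec.n_scored_block[b]
            for b in rec.prop_correct_block
        )
        assert weighted / rec.n_scored == pytest.approx(
            rec.prop_correct_overall, abs=1e-12
        )


class TestTwoWayAnova:
    def test_matches_hand_computed_sums_of_squares(self):
        # balanced 2x2 with 3 observations per cell: classic SS formulas
        data = {
            ("male", "low"): [0.70, 0.75, 0.80],
            ("male", "high"): [0.85, 0.80, 0.90],
            ("female", "low"): [0.72, 0.78, 0.74],
            ("female", "high"): [0.60, 0.66, 0.63],
        }
        rows = [
            {"sex": sex, "stress_group": st, "prop_correct": v}
            for (sex, st), values in data.items()
            for v in values
        ]
        perf = pd.DataFrame(rows)
        table = two_way_anova(perf)

        values = np.array(list(data.values()))  # (4 cells, 3 reps)
        grand = values.mean()
        cell_means = values.mean(axis=1)
        sex_means = {
            "male": values[:2].mean(), "female": values[2:].mean()
        }
        stress_means = {
            "low": values[[0, 2]].mean(), "high": values[[1, 3]].mean()
        }
        n_per_cell, n_per_margin = 3, 6
        ss_sex = n_per_margin * sum(
            (m - grand) ** 2 for m in sex_means.values()
        )
        ss_stress = n_per_margin * sum(
            (m - grand) ** 2 for m in stress_means.values()
        )
        ss_cells = n_per_cell * ((cell_means - grand) ** 2).sum()
        ss_inter = ss_cells - ss_sex - ss_stress
        ss_err = ((values - cell_means[:, None]) ** 2).sum()
        df_err = 8
        for term, ss in (("sex", ss_sex), ("stress", ss_stress),
                         ("sex:stress", ss_inter)):
            f_hand = (ss / 1) / (ss_err / df_err)
            assert table.loc[term, "F"] == pytest.approx(f_hand, abs=1e-8)

    def test_single_level_factor_rejected(self):
        perf = pd.DataFrame(
            {"sex": ["male"] * 4, "stress_group": ["low", "low", "high", "high"],
             "prop_correct": [0.5, 0.6, 0.7, 0.8]}
        )
        with pytest.raises(AnalysisError, match="sex"):
            two_way_anova(perf)


def test_group_contrasts_structure():
    subjects = generate_cohort(
        CohortSpec(n_per_group=6, groups=_default_groups(), seed=23)
    )
    report = group_contrasts(performance_table(subjects))
    assert {"sex", "stress", "sex:stress"} <= set(report.anova.index)
    assert set(report.posthoc.stress_group) == {"low", "high"}
    assert set(report.blockwise) == {"low", "high"}
    # mixed ANOVA table has the between (sex) and within (block) effects
    assert {"sex", "block"} <= set(report.blockwise["high"]["Source"])


@pytest.fixture(scope="module")
def cohort():
    subjects = generate_cohort(default_spec_with_seed(31))
    perf = performance_table(subjects)
    params = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "alpha": s.generative_params.alpha,
                "gamma": s.generative_params.gamma,
            }
            for s in subjects
        ]
    )
    return perf, params


class TestSexDifferenceGlm:

    def test_flipped_coding_negates_coefficient(self, cohort):
        perf, params = cohort
        a = sex_difference_glm(perf, params, male_code=1)
        b = sex_difference_glm(perf, params, male_code=0)
        assert np.allclose(a.coef_sex.values, -b.coef_sex.values)
        assert np.allclose(a.se_sex.values, b.se_sex.values)

    def test_scopes_cover_blocks(self, cohort):
        perf, params = cohort
        out = sex_difference_glm(perf, params)
        assert set(out.scope) == {"all", "block_1", "block_2", "block_3"}
        assert set(out.covariates) == {"none", "alpha", "gamma"}

    def test_missing_covariate_column_rejected(self, cohort):
        perf, _ = cohort
        with pytest.raises(AnalysisError):
            sex_difference_glm(perf, None, covariate_sets=[("gamma",)])

    def test_gamma_covariate_absorbs_gamma_driven_sex_gap(self):
        """On cohorts where only the weighting slope differs by sex under
        high stress (means 2.5 vs 1.5, inside the monotone range of the
        performance curve), adjusting for fitted gamma attenuates the sex
        coefficient far more than adjusting for fitted alpha."""
        att_gamma, att_alpha = [], []
        for seed in (0, 1, 2, 3):
            subjects = generate_cohort(gamma_contrast_spec(seed, n_per_group=96))
            perf = performance_table(subjects)
            high = [s for s in subjects if s.stress_group == "high"]
            rows = []
            for i, s in enumerate(high):
                f = fit_map("s1w", s.trials, n_restarts=20, seed=5000 + i)
                rows.append(
                    {"subject_id": s.subject_id, "alpha": f.params.alpha,
                     "gamma": f.params.gamma}
                )
            glm = sex_difference_glm(perf, pd.DataFrame(rows))
            g = glm[glm.scope == "all"].set_index("covariates")
            att_gamma.append(g.loc["gamma", "attenuation"])
            att_alpha.append(g.loc["alpha", "attenuation"])
        assert np.mean(att_gamma) > 0.3
        assert np.mean(att_gamma) > np.mean(att_alpha) + 0.2
        assert np.mean(att_alpha) < 0.4


def default_spec_with_seed(seed):
    return CohortSpec(n_per_group=16, groups=_default_groups(), seed=seed)


def gamma_contrast_spec(seed, n_per_group=32):
    """Only gamma differs by sex under high stress; both sexes sit in the
    monotone-declining part of the performance-vs-gamma curve."""
    groups = {}
    for (sex, st), gp in _default_groups().items():
        gamma = 2.5 if (sex, st) == ("female", "high") else 1.5
        groups[(sex, st)] = dataclasses.replace(
            gp, alpha_mean=0.10, gamma_mean=gamma, gamma_sd=0.4
        )
    return CohortSpec(n_per_group=n_per_group, groups=groups, seed=seed)


def wide_gamma_spec(seed, n_per_group=48):
    """All cells share a wide, performance-degrading gamma distribution."""
    groups = {
        key: dataclasses.replace(gp, gamma_mean=2.2, gamma_sd=0.8)
        for key, gp in _default_groups().items()
    }
    return CohortSpec(n_per_group=n_per_group, groups=groups, seed=seed)


@pytest.fixture(scope="module")
def fitted_cohort():
    subjects = generate_cohort(wide_gamma_spec(41))
    perf = performance_table(subjects)
    rows = []
    for i, s in enumerate(subjects):
        f = fit_map("s1w", s.trials, n_restarts=20, seed=6000 + i)
        rows.append(
            {"subject_id": s.subject_id, "alpha": f.params.alpha,
             "gamma": f.params.gamma}
        )
    return perf, pd.DataFrame(rows)


class TestParameterPerformanceRegression:

    def test_gamma_degrades_performance_in_both_sexes(self, fitted_cohort):
        perf, params = fitted_cohort
        out = parameter_performance_regression(perf, params).set_index(
            ["sex", "parameter"]
        )
        for sex in ("male", "female"):
            row = out.loc[(sex, "gamma")]
            assert row.slope < 0
            assert row.r2 > 0 and row.p < 0.01

    def test_permuted_labels_break_association(self, fitted_cohort):
        perf, params = fitted_cohort
        rng = np.random.default_rng(0)
        n_sig = 0
        n_perm = 100
        for _ in range(n_perm):
            shuffled = params.copy()
            shuffled["gamma"] = rng.permutation(shuffled["gamma"].values)
            out = parameter_performance_regression(
                perf, shuffled, parameters=("gamma",), by_sex=False
            )
            n_sig += out.p.iloc[0] < 0.05
        assert n_sig <= 0.15 * n_perm

    def test_constant_predictor_flagged(self, fitted_cohort):
        perf, params = fitted_cohort
        const = params.copy()
        const["gamma"] = 1.0
        out = parameter_performance_regression(perf, const, parameters=("gamma",))
        assert out.flagged.all()
        assert (out.r2 == 0).all()

    def test_small_stratum_skipped(self):
        perf = pd.DataFrame(
            {"subject_id": ["a", "b"], "sex": ["male", "male"],
             "prop_correct": [0.7, 0.8]}
        )
        params = pd.DataFrame(
            {"subject_id": ["a", "b"], "gamma": [1.0, 2.0]}
        )
        with pytest.warns(UserWarning):
            out = parameter_performance_regression(perf, params)
        assert out.empty


class TestValidateModelRegression:
    def test_model_generated_data_shows_both_effects(self):
        subjects = generate_cohort(default_spec_with_seed(51))
        fitted = {s.subject_id: s.generative_params for s in subjects}
        _, group = validate_model_regression(subjects, fitted)
        g = group.set_index("predictor")
        assert g.loc["magnitude", "mean_coef"] > 0
        assert g.loc["probability", "mean_coef"] > 0
        assert g.loc["magnitude", "p"] < 1e-3
        assert g.loc["probability", "p"] < 1e-3

    def test_random_agents_show_no_effects(self):
        from stressrl import null_cohort_spec

        subjects = generate_cohort(null_cohort_spec(n_per_group=10, seed=52))
        fitted = {
            s.subject_id: AgentParams("s1w", alpha=0.1, gamma=1.2, beta=0.1)
            for s in subjects
        }
        per_subject, group = validate_model_regression(subjects, fitted)
        g = group.set_index("predictor")
        assert g.loc["magnitude", "p"] > 0.01
        assert g.loc["probability", "p"] > 0.01

    def test_magnitude_only_agent(self):
        """An agent that ignores probability (near-flat weighting) shows a
        magnitude effect but no probability effect when validated with
        identity weighting."""
        cfg = TaskConfig()
        rng = np.random.default_rng(53)
        agent = AgentParams("s1w", alpha=0.2, gamma=0.02, beta=0.15)
        probe = AgentParams("s1w", alpha=0.2, gamma=1.0, beta=0.15)
        from stressrl import Subject

        subjects = [
            Subject(f"s{i}", "female", 10, agent,
                    simulate_agent(agent, cfg, rng=rng))
            for i in range(30)
        ]
        fitted = {s.subject_id: probe for s in subjects}
        _, group = validate_model_regression(subjects, fitted)
        g = group.set_index("predictor")
        assert g.loc["magnitude", "mean_coef"] > 0
        assert g.loc["magnitude", "p"] < 1e-3
        assert g.loc["probability", "p"] > 0.01
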