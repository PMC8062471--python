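"""Model-free and model-based group analysis.

Covers the downstream statistics run on a (real or synthetic) cohort:

- proportion of "correct" choices — choosing the option whose true
  expected value (true reward probability x displayed magnitude) is
  larger — overall and per block;
- two-way sex x stress ANOVA with pairwise post-hoc contrasts and a
  block-wise repeated-measures variant;
- the covariate-adjusted sex-difference GLM under high stress (does
  controlling fitted gamma, or fitted alpha, absorb the sex effect?);
- per-sex regressions of performance on fitted parameters;
- the model-validation regression: per-subject logistic regressions of
  choice on magnitude difference and model-estimated (weighted)
  probability difference, summarized by group-level one-sample tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .cohort import Subject
from .models import AgentParams, run_model, weight_probability
from .task import OPTION_A, TaskConfig, TrialRecord, expected_values


class AnalysisError(ValueError):
    """The requested contrast cannot be computed from the given data."""


@dataclass
class PerformanceRecord:
    """Correct-choice proportions for one subject.

    Proportions are computed over responded, non-tied trials only; trials
    where both options have exactly equal true expected value are excluded
    from the denominator.
    """

    subject_id: str
    prop_correct_overall: float
    prop_correct_block: dict[int, float]
    n_responded: int
    n_scored: int
    n_scored_block: dict[int, int] = field(default_factory=dict)
    flagged: bool = False


def score_correct_choices(
    trials: Sequence[TrialRecord],
    config: TaskConfig,
    subject_id: str = "",
) -> PerformanceRecord:
    """Score a trial log against the true expected values.

    A trial is correct iff the chosen option's true probability x magnitude
    strictly exceeds the other option's; exact ties and no-response trials
    are excluded from the denominator.
    """
    correct: dict[int, int] = {}
    scored: dict[int, int] = {}
    n_responded = 0
    for rec in trials:
        if not rec.response_made or rec.chosen is None:
            continue
        n_responded += 1
        ev_a, ev_b = expected_values(rec, config)
        if ev_a == ev_b:
            continue
        better = OPTION_A if ev_a > ev_b else "B"
        scored[rec.block_index] = scored.get(rec.block_index, 0) + 1
        if rec.chosen == better:
            correct[rec.block_index] = correct.get(rec.block_index, 0) + 1
    n_scored = sum(scored.values())
    if n_scored == 0:
        warnings.warn(
            f"subject {subject_id or '?'}: no scorable trials; "
            "proportion correct undefined",
            stacklevel=2,
        )
        return PerformanceRecord(subject_id, np.nan, {}, n_responded, 0, {}, True)
    prop_block = {
        b: correct.get(b, 0) / n for b, n in sorted(scored.items())
    }
    overall = sum(correct.values()) / n_scored
    return PerformanceRecord(
        subject_id, overall, prop_block, n_responded, n_scored, dict(scored)
    )


def performance_table(
    subjects: Sequence[Subject], config: Optional[TaskConfig] = None
) -> pd.DataFrame:
    """Per-subject performance with sex/stress metadata, one row each."""
    config = config or TaskConfig()
    rows = []
    for s in subjects:
        rec = score_correct_choices(s.trials, config, s.subject_id)
        row = {
            "subject_id": s.subject_id,
            "sex": s.sex,
            "stress_group": s.stress_group,
            "pss": s.pss,
            "prop_correct": rec.prop_correct_overall,
            "n_responded": rec.n_responded,
            "n_scored": rec.n_scored,
        }
        for b, p in rec.prop_correct_block.items():
            row[f"prop_block_{b}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ContrastReport:
    """Two-way ANOVA, post-hoc contrasts and block-wise variant."""

    anova: pd.DataFrame
    posthoc: pd.DataFrame
    blockwise: dict[str, pd.DataFrame]


def two_way_anova(perf: pd.DataFrame, dv: str = "prop_correct") -> pd.DataFrame:
    """Sex x stress factorial ANOVA (type-II sums of squares) on ``dv``."""
    for factor in ("sex", "stress_group"):
        if factor not in perf.columns or perf[factor].nunique() < 2:
            raise AnalysisError(f"factor {factor!r} missing or single-level")
    model = smf.ols(f"{dv} ~ C(sex) * C(stress_group)", data=perf).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={
            "C(sex)": "sex",
            "C(stress_group)": "stress",
            "C(sex):C(stress_group)": "sex:stress",
        }
    )
    return table


def group_contrasts(
    perf: pd.DataFrame,
    dv: str = "prop_correct",
    correction: Optional[str] = None,
) -> ContrastReport:
    """Factorial contrasts on per-subject performance (or any ``dv``).

    Post-hoc sex contrasts within each stress level are uncorrected
    pairwise t-tests by default; pass ``correction="bonferroni"`` (or any
    method known to statsmodels' multipletests) to adjust them. The
    block-wise variant is a mixed ANOVA per stress level with block as the
    within-subject factor and sex between subjects.
    """
    anova = two_way_anova(perf, dv)
    rows = []
    for stress, sub in perf.groupby("stress_group"):
        male = sub.loc[sub.sex == "male", dv].dropna()
        female = sub.loc[sub.sex == "female", dv].dropna()
        if len(male) < 2 or len(female) < 2:
            warnings.warn(
                f"stress level {stress!r}: a sex cell has <2 subjects; "
                "contrast skipped",
                stacklevel=2,
            )
            continue
        t, p = stats.ttest_ind(male, female)
        rows.append(
            {
                "stress_group": stress,
                "mean_male": male.mean(),
                "mean_female": female.mean(),
                "t": t,
                "p": p,
            }
        )
    posthoc = pd.DataFrame(rows)
    if correction and not posthoc.empty:
        from statsmodels.stats.multitest import multipletests

        posthoc["p_adj"] = multipletests(posthoc["p"], method=correction)[1]

    block_cols = sorted(c for c in perf.columns if c.startswith("prop_block_"))
    blockwise: dict[str, pd.DataFrame] = {}
    if block_cols:
        long = perf.melt(
            id_vars=["subject_id", "sex", "stress_group"],
            value_vars=block_cols,
            var_name="block",
            value_name="prop",
        ).dropna(subset=["prop"])
        for stress, sub in long.groupby("stress_group"):
            if sub["sex"].nunique() < 2:
                continue
            blockwise[stress] = pg.mixed_anova(
                data=sub,
                dv="prop",
                within="block",
                between="sex",
                subject="subject_id",
            )
    return ContrastReport(anova=anova, posthoc=posthoc, blockwise=blockwise)


def sex_difference_glm(
    perf: pd.DataFrame,
    fitted_params: Optional[pd.DataFrame] = None,
    covariate_sets: Sequence[tuple[str, ...]] = ((), ("alpha",), ("gamma",)),
    stress_level: str = "high",
    male_code: int = 1,
) -> pd.DataFrame:
    """Sex coefficient for performance under one stress level, with and
    without fitted-parameter covariates.

    Fits OLS ``performance ~ sex_indicator (+ covariates)`` on the given
    stress subset, overall and per block. The sex indicator codes male as
    ``male_code`` (1 by default, so the coefficient is the male - female
    performance difference). The attenuation statistic for an adjusted
    model is ``1 - b_adjusted / b_unadjusted``.

    ``fitted_params`` must hold one row per subject with the covariate
    columns (fitted, not generative, parameters).
    """
    sub = perf[perf.stress_group == stress_level].copy()
    if sub.empty:
        raise AnalysisError(f"no subjects in stress level {stress_level!r}")
    if male_code not in (0, 1):
        raise AnalysisError("male_code must be 0 or 1")
    sub["sex_male"] = np.where(sub.sex == "male", male_code, 1 - male_code)
    if fitted_params is not None:
        sub = sub.merge(fitted_params, on="subject_id", how="left", suffixes=("", "_fit"))
    scopes = {"all": "prop_correct"}
    for col in sorted(c for c in sub.columns if c.startswith("prop_block_")):
        scopes[f"block_{col.rsplit('_', 1)[1]}"] = col
    rows = []
    for scope, dv in scopes.items():
        base_coef = None
        for covs in covariate_sets:
            missing = [c for c in covs if c not in sub.columns]
            if missing:
                raise AnalysisError(f"covariate columns missing: {missing}")
            cols = ["sex_male", *covs]
            data = sub.dropna(subset=[dv, *cols])
            exog = sm.add_constant(data[cols])
            cond = np.linalg.cond(exog.to_numpy())
            if cond > 1e6:
                warnings.warn(
                    f"ill-conditioned design (cond={cond:.1e}) for "
                    f"covariates {covs}",
                    stacklevel=2,
                )
            res = sm.OLS(data[dv], exog).fit()
            coef = res.params["sex_male"]
            if not covs:
                base_coef = coef
            rows.append(
                {
                    "scope": scope,
                    "covariates": "+".join(covs) if covs else "none",
                    "coef_sex": coef,
                    "se_sex": res.bse["sex_male"],
                    "p_sex": res.pvalues["sex_male"],
                    "n": int(res.nobs),
                    "attenuation": (
                        np.nan if base_coef in (None, 0) or not covs
                        else 1.0 - coef / base_coef
                    ),
                }
            )
    return pd.DataFrame(rows)


def parameter_performance_regression(
    perf: pd.DataFrame,
    fitted_params: pd.DataFrame,
    parameters: Sequence[str] = ("gamma", "alpha"),
    by_sex: bool = True,
) -> pd.DataFrame:
    """Simple linear regressions of performance on fitted parameters.

    One regression per (sex stratum, parameter): slope, r^2 and p. Strata
    with fewer than 3 subjects are skipped; a constant predictor yields a
    flagged row with undefined slope and r^2 = 0.
    """
    data = perf.merge(fitted_params, on="subject_id", how="inner")
    strata = data.groupby("sex") if by_sex else [("all", data)]
    rows = []
    for sex, sub in strata:
        for param in parameters:
            if param not in sub.columns:
                continue
            d = sub.dropna(subset=["prop_correct", param])
            if len(d) < 3:
                warnings.warn(
                    f"stratum {sex!r}: n={len(d)} < 3, regression on "
                    f"{param!r} skipped",
                    stacklevel=2,
                )
                continue
            if d[param].nunique() == 1:
                rows.append(
                    {
                        "sex": sex,
                        "parameter": param,
                        "slope": np.nan,
                        "r2": 0.0,
                        "p": np.nan,
                        "n": len(d),
                        "flagged": True,
                    }
                )
                continue
            res = stats.linregress(d[param], d["prop_correct"])
            rows.append(
                {
                    "sex": sex,
                    "parameter": param,
                    "slope": res.slope,
                    "r2": res.rvalue**2,
                    "p": res.pvalue,
                    "n": len(d),
                    "flagged": False,
                }
            )
    return pd.DataFrame(rows)


def validate_model_regression(
    subjects: Sequence[Subject],
    fitted: dict[str, AgentParams],
    **model_options,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Does the fitted model's probability estimate actually predict choice?

    For each subject, a logistic regression of the chosen-option indicator
    (option A = 1) on the magnitude difference and the model-estimated
    weighted-probability difference between the options, both from the
    subject's fitted winning-model parameters. Subjects with separated or
    non-converged regressions are flagged and excluded from the group-level
    one-sample t-tests on the two coefficient populations.

    Returns ``(per_subject, group_level)`` tables.
    """
    rows = []
    for s in subjects:
        params = fitted[s.subject_id]
        trace, _ = run_model(params, s.trials, **model_options)
        gamma = params.gamma if params.model_name.endswith("w") else 1.0
        y, mag_diff, prob_diff = [], [], []
        for i, rec in enumerate(s.trials):
            if not rec.response_made or rec.chosen is None:
                continue
            y.append(1.0 if rec.chosen == OPTION_A else 0.0)
            mag_diff.append((rec.magnitude_A - rec.magnitude_B) / 100.0)
            f_a = weight_probability(trace.p_pred[i], gamma)
            f_b = weight_probability(1.0 - trace.p_pred[i], gamma)
            prob_diff.append(f_a - f_b)
        exog = sm.add_constant(
            pd.DataFrame({"mag_diff": mag_diff, "prob_diff": prob_diff})
        )
        flagged = False
        coef_mag = coef_prob = np.nan
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(np.asarray(y), exog).fit(disp=0, maxiter=200)
            coef_mag = res.params["mag_diff"]
            coef_prob = res.params["prob_diff"]
            if not res.mle_retvals.get("converged", True) or np.abs(
                res.params
            ).max() > 1e3:
                flagged = True
        except Exception:
            flagged = True
        rows.append(
            {
                "subject_id": s.subject_id,
                "coef_magnitude": coef_mag,
                "coef_probability": coef_prob,
                "flagged": flagged,
            }
        )
    per_subject = pd.DataFrame(rows)
    ok = per_subject[~per_subject.flagged]
    group_rows = []
    for col, label in (
        ("coef_magnitude", "magnitude"),
        ("coef_probability", "probability"),
    ):
        vals = ok[col].dropna()
        t, p = stats.ttest_1samp(vals, 0.0) if len(vals) > 1 else (np.nan, np.nan)
        group_rows.append(
            {
                "predictor": label,
                "mean_coef": vals.mean(),
                "t": t,
                "p": p,
                "n": len(vals),
                "n_flagged": int(per_subject.flagged.sum()),
            }
        )
    return per_subject, pd.DataFrame(group_rows)
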