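# Methods

This note documents the models, numerical choices and validation design of
`stressrl`, including the places where the design was genuinely open and
what the synthetic-data experiments do and do not show.

## Task model

The simulated task is a 60-trial, two-option probabilistic reward task:
three blocks of 20 trials, within each block one option rewarded with
probability 0.75 and the other 0.25, the assignment redrawn uniformly at
each block start. Magnitudes are complementary integers (R, 100 − R) with R
uniform on 1..99. Exactly one option is rewarded per trial, pre-drawn
independently of the choice. A no-response trial earns nothing and is
excluded from likelihoods.

Two details of the original task description are under-specified and were
fixed as follows:

- **Repeat-choice magnitude adjustment.** The magnitude of a stimulus chosen
  twice in a row is "reduced"; by how much is not stated. We redraw it
  uniformly from the lower half of the range, {1..49}, which guarantees a
  reduction in expectation while preserving magnitude complementarity. The
  run counter resets at block boundaries and after a no-response trial.
- **Option identity.** Options are latent identities A/B; screen position is
  cosmetic and not modeled.

## Learning models

Eight models, all learning the predicted reward probability p(A) of one
option with p(B) = 1 − p(A) and p initialized to 0.5:

- **s1**: Rescorla–Wagner, p ← p + α(r − p) on the chosen option.
- **s2**: separate rates α₊/α₋ for positive/negative prediction errors
  (ties use α₊; the update is then zero anyway).
- **d1**: Pearce–Hall. Associability S tracks recent unsigned prediction
  errors, S ← (1 − μ)S + μ|δ|, and the effective rate is κ·S.
- **d2**: one rate for trials 1–30, another for 31–60 (global trial index).
- **s1w/s2w/d1w/d2w**: the same plus a linear probability-weighting slope γ,
  F(p, γ) = clip(γ(p − 0.5) + 0.5, 0, 1), applied when forming expected
  values Q = magnitude × F(p, γ).

Choices are sigmoidal in β(Q_A − Q_B). Three open details:

- **Update source**: only the chosen option's reward indicator updates the
  learned probability (the update equations condition on the choice), even
  though the task's feedback reveals the rewarded stimulus either way.
- **Block reset** (`reset_at_block`, default on): the learned probability
  (and associability) re-initializes at block boundaries, because the
  contingency is re-randomized there. The alternative — carrying state
  across blocks — is available behind the flag; generation and fitting must
  use the same setting, and all defaults do.
- **Pearce–Hall ordering** (`associability_first`, default on): the
  associability is updated with the current |δ| first and the resulting rate
  applied to the current trial's value update, matching the t+1 indexing of
  the rate; the alternative ordering (rate from the pre-update associability)
  is behind the flag. Initial associability S₀ = 1; the effective rate is
  clamped to [0, 1] so probabilities stay in range.

No-response trials contribute no likelihood term and trigger no update.

## Priors and MAP estimation

Learning rates (α, α₊, α₋, α₁, α₂) carry Beta(4.6, 50) priors, γ a
Gamma(1.9, scale 1.0), β a Gamma(2.8, scale 0.05), and μ, κ uniform
Beta(1, 1). Gamma distributions are parameterized shape–scale, so the β
prior has mean 0.14 — appropriate for expected values on a 0–100 point
scale (β·ΔQ is then order 1). An alternative Beta(2, 2) rate-prior set
(`flat_rates`) is included for sensitivity runs.

MAP estimation maximizes log-likelihood + log prior over the *raw*
constrained parameters, with −∞ outside any prior's support. The optimizer
is a multi-start Nelder–Mead simplex (classic fminsearch scheme: reflection
1, expansion 2, contraction 0.5, shrink 0.5; initial simplex perturbs each
coordinate by 5%; TolX = TolFun = 1e−4; at most 400·k iterations per start).
Starts are drawn from the priors. The default is 100 restarts; tests and
examples use 15–50 because on these 2–4-parameter posteriors the optimum
found stops improving well before that (30 restarts already match a
200³ grid search to < 0.05 nats, and a 25-restart run matches a 50-restart
scipy reference to ~1e−7). The likelihood and the simplex loop are compiled
with numba; a pure-Python reference implementation (`models.run_model`) is
the documented semantics, and tests pin the two paths together at 1e−10.

## Laplace model evidence

log Z ≈ log p(data, θ_MAP) + (k/2)·log 2π − ½·log det H, with H the Hessian
of the negative log posterior by central finite differences (relative step
1e−3 with an absolute scale floor of 1e−2 per parameter — the floor keeps
the stencil above round-off for near-zero parameters; one retry at 1e−2,
then the subject × model cell is flagged). Stencil points falling within two
steps of a support bound are nudged inside.

The approximation requires an interior optimum. When the MAP is pinned to a
support boundary (within 1e−4) the evidence is reported missing and the cell
flagged. This case is common and structural: fitting the Pearce–Hall models
to data generated by a constant-rate model drives μ to 0 (constant
associability) or 1 (fully error-driven), both on the boundary of the
uniform prior. The local curvature there is near zero in the pinned
direction, and a Gaussian integral over it would overstate the evidence by
1–3 nats — enough to flip model comparisons — so flagging is the only
defensible treatment.

Model comparison averages evidence per model over **complete cases**
(subjects with a valid evidence for every model): averaging each model over
its own non-flagged subjects would bias the comparison toward models whose
hardest subjects were flagged. More than 10% missing cells is an error by
default; recovery experiments, where dynamic-model boundary fits are
expected, raise the threshold explicitly.

## Synthetic cohorts

The generator builds four sex × stress cells. Per-cell parameters are drawn
from normals truncated to the model support; Perceived Stress Scale (PSS,
0–40) scores from a discretized truncated normal on the cell's side of the
high-stress threshold (≥ 19). Defaults:

- γ means: high-stress female 1.6, high-stress male 1.1, both low-stress
  cells 1.2; SD 0.3 — the qualitative effect structure the analysis is
  meant to detect (the key manipulated quantity).
- α means: low-stress female 0.15 vs male 0.08 (low-stress females learn
  faster); both high-stress cells 0.10; SD 0.03.
- β: mean 0.10, SD 0.03 in all cells — near the prior mean, giving agents
  that perform clearly above chance (~0.79 proportion correct) without
  being deterministic.
- PSS: low cells 14.89 ± 3.06, high cells 23.17 ± 3.79.

These are generator defaults chosen to emulate a plausible study
population, not estimates of any real one. A `null_cohort_spec` gives four
identical cells of β = 0 (coin-flip) agents for type-I-error calibration.

What the generator does *not* emulate: reaction times, attention lapses and
non-stationary motivation, any correlation between parameters and PSS
beyond the cell structure, and real no-response behavior (simulated agents
always respond; the no-response code paths are exercised with constructed
logs).

## Validation design and problem sizes

- **Likelihood oracle**: `run_model` vs an independently written naive
  reimplementation, 1e−10 on random instances of all eight models.
- **Optimizer oracle**: MAP vs a dense 200×200×200 grid search of the same
  posterior on random s1w instances, within 0.05 nats.
- **Evidence oracle**: the Laplace routine vs the exact Beta–Bernoulli
  marginal likelihood at n = 60, within 0.1 nats.
- **Parameter recovery**: on the default 64-subject cohort, generative vs
  fitted γ rank-correlate at ≥ 0.6 (measured ≈ 0.71); s1's α at truth 0.1,
  β 0.1 recovers with median error < 0.1 over 100 replicates.
- **Model recovery**: 20 cohorts of 64 s1w agents with parameters drawn
  from the fitting priors; the winner must be s1w in ≥ 80% of cohorts
  (measured 18/20). Prior-drawn parameters are the canonical recovery
  design: they span the γ range the priors consider plausible (~0.3–4),
  where the weighting parameter is clearly identifiable. Under the default
  *group-structured* cohort the γ means sit in 1.1–1.6, where s1w's
  expected mean-evidence margin over s2 is only ≈ 0.12 nats; cohorts of
  several hundred subjects would be needed for reliable selection, so model
  recovery is tested under the prior-drawn design and the margin analysis
  is recorded here.
- **Analysis calibration**: the sex × stress interaction on the null
  generator rejects at 4.7% (1,000-replicate estimate; the 200-replicate
  test band is 3–7%).

### Known limitation: the covariate-attenuation analysis

The pipeline reproduces the logic "controlling fitted γ (but not fitted α)
absorbs the high-stress sex difference in performance", but under the
default cohort this is a fragile quantity. Two structural reasons,
established by simulation:

1. The performance–γ curve of this task is shallow and non-monotonic near
   γ = 1 (≈ 0.795 at γ 0.9–1.3, 0.772 at 1.6, 0.757 at 2.0): a 1.6-vs-1.1
   contrast moves performance by only ≈ 0.02, below cohort-level sampling
   noise at n = 64 (sex-coefficient SD ≈ 0.024). The attenuation ratio of a
   noise-dominated coefficient is unstable, and remains so even pooling
   hundreds of subjects (true-γ adjustment attenuates 0.3–0.9 across
   seeds).
2. Fitted γ carries estimation error at 60 trials, so covariate adjustment
   is additionally incomplete (classical errors-in-variables).

The attenuation property is therefore demonstrated robustly on cohorts
whose γ contrast lies inside the monotone region of the performance curve
with a wide within-group spread (means 2.5 vs 1.5, SD 0.4, large cells),
where mean γ-attenuation ≈ 0.7 against α-attenuation ≈ 0.2; on the default
cohort the corresponding check is seed-sensitive.

## Degenerate inputs and tie-breaks

- Tied true expected values (possible at magnitudes 25/75) are excluded
  from the correctness denominator.
- Model-comparison ties break toward fewer free parameters.
- Subjects with no scorable trials, empty stress groups, constant
  regression predictors, and separated per-subject logistic regressions are
  flagged/skipped with warnings rather than failing the run.
- Post-hoc contrasts are uncorrected pairwise t-tests by default (a
  multiple-testing correction is available); the two-way ANOVA uses type-II
  sums of squares, appropriate for the near-balanced synthetic designs.
- The mixed-effects validation of the winning model is implemented as the
  two-stage summary-statistics version: per-subject
  logistic regressions of choice on magnitude and model-weighted
  probability differences, then group-level one-sample t-tests on the
  coefficients.
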