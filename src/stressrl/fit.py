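"""MAP fitting and Laplace-approximation model comparison.

Each subject x model pair is fitted by maximizing the log posterior
(trial-level log-likelihood plus log prior densities) with a multi-start
Nelder-Mead simplex search operating directly on the constrained
parameters; points outside any prior's support score ``-inf``. Model
evidence is then approximated at the MAP with a Laplace (Gaussian)
approximation,

    log Z ~= log p(data, theta_MAP) + (k/2) log 2*pi - (1/2) log det H,

where H is the Hessian of the negative log posterior, computed by central
finite differences. The evidence trades off fit quality against the number
of free parameters k and is averaged across subjects to select the winning
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .models import (
    MODEL_FREE_PARAMS,
    MODEL_NAMES,
    S_INIT,
    AgentParams,
    ParameterError,
    TrialRecord,
    log_likelihood_fast,
    run_model,
    trials_to_arrays,
)
from .priors import PriorSpec, check_coverage, get_priors

LOG_2PI = math.log(2.0 * math.pi)


class FitError(RuntimeError):
    """No restart of the optimizer produced a usable optimum."""


class ComparisonError(RuntimeError):
    """Too many subject x model evidences are missing to compare models."""


@dataclass
class FitResult:
    """MAP fit of one model to one subject's trial log."""

    model_name: str
    params: AgentParams
    log_lik: float
    log_post: float
    log_evidence: Optional[float] = None
    hessian_ok: Optional[bool] = None
    n_restarts_used: int = 0
    n_converged: int = 0
    subject_id: Optional[str] = None
    options: dict = field(default_factory=dict, repr=False)

    @property
    def theta(self) -> np.ndarray:
        return self.params.to_vector()


def log_posterior(
    params: AgentParams,
    trials: Sequence[TrialRecord],
    priors: PriorSpec | str = "default",
    **model_options,
) -> float:
    """Log posterior density (up to the marginal-likelihood constant).

    Sum of the :func:`stressrl.models.run_model` log-likelihood and the log
    prior density of every free parameter; ``-inf`` outside any support.
    """
    priors = get_priors(priors)
    check_coverage(params.model_name, priors)
    lp = 0.0
    for name in params.free_names:
        lp += priors[name].logpdf(getattr(params, name))
        if lp == -math.inf:
            return -math.inf
    _, ll = run_model(params, trials, **model_options)
    return ll + lp


def _make_neg_log_post(
    model_name: str,
    trials: Sequence[TrialRecord],
    priors: PriorSpec,
    model_options: dict,
) -> Callable[[np.ndarray], float]:
    """Fast negative-log-posterior objective over the raw parameter vector."""
    arrays = trials_to_arrays(trials)
    names = MODEL_FREE_PARAMS[model_name]
    prior_list = [priors[n] for n in names]

    def neg_log_post(theta: np.ndarray) -> float:
        lp = 0.0
        for value, prior in zip(theta, prior_list):
            lp += prior.logpdf(value)
            if lp == -math.inf:
                return math.inf
        try:
            params = AgentParams.from_vector(model_name, theta)
        except ParameterError:
            return math.inf
        ll = log_likelihood_fast(params, arrays, **model_options)
        return -(ll + lp)

    return neg_log_post


def _draw_start(
    model_name: str, priors: PriorSpec, rng: np.random.Generator
) -> np.ndarray:
    return np.array(
        [priors[n].sample(rng) for n in MODEL_FREE_PARAMS[model_name]], dtype=float
    )


def _encode_priors(
    model_name: str, priors: PriorSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pack the model's priors into (family, p1, p2) arrays for the kernel."""
    from .priors import BetaPrior, GammaPrior

    names = MODEL_FREE_PARAMS[model_name]
    fam = np.empty(len(names), dtype=np.int64)
    p1 = np.empty(len(names))
    p2 = np.empty(len(names))
    for i, name in enumerate(names):
        prior = priors[name]
        if isinstance(prior, BetaPrior):
            fam[i], p1[i], p2[i] = _kernels.FAM_BETA, prior.a, prior.b
        elif isinstance(prior, GammaPrior):
            fam[i], p1[i], p2[i] = _kernels.FAM_GAMMA, prior.shape, prior.scale
        else:
            raise TypeError(f"unsupported prior type {type(prior)!r} for {name}")
    return fam, p1, p2


def fit_map(
    model_name: str,
    trials: Sequence[TrialRecord],
    priors: PriorSpec | str = "default",
    n_restarts: int = 100,
    seed: Optional[int] = None,
    *,
    xatol: float = 1e-4,
    fatol: float = 1e-4,
    subject_id: Optional[str] = None,
    **model_options,
) -> FitResult:
    """Multi-start MAP estimation for one subject and model.

    Runs a Nelder-Mead simplex search from ``n_restarts`` random starting
    points drawn from the priors and keeps the best optimum. Deterministic
    given ``seed``. ``model_options`` (``reset_at_block``, ``s0``,
    ``associability_first``) are forwarded to the likelihood.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    priors = get_priors(priors)
    check_coverage(model_name, priors)
    rng = np.random.default_rng(seed)
    k = len(MODEL_FREE_PARAMS[model_name])
    starts = np.vstack([_draw_start(model_name, priors, rng) for _ in range(n_restarts)])
    params0 = AgentParams.from_vector(model_name, starts[0])
    base, weighted, *_ = _kernels.encode(params0)
    fam, p1, p2 = _encode_priors(model_name, priors)
    arrays = trials_to_arrays(trials)
    opts = {
        "reset_at_block": True,
        "s0": S_INIT,
        "associability_first": True,
        **model_options,
    }
    best_theta, best_fun, n_converged = _kernels.multistart_nelder_mead(
        starts,
        base,
        weighted,
        fam,
        p1,
        p2,
        arrays["chosen"],
        arrays["reward"],
        arrays["responded"],
        arrays["mag_a"],
        arrays["mag_b"],
        arrays["block"],
        arrays["tidx"],
        int(arrays["tidx"][-1]),
        opts["reset_at_block"],
        opts["s0"],
        opts["associability_first"],
        xatol,
        fatol,
        400 * k,
    )
    if n_converged == 0 or not np.all(np.isfinite(best_theta)):
        raise FitError(
            f"no converged optimum for model {model_name} "
            f"after {n_restarts} restarts"
        )
    params = AgentParams.from_vector(model_name, best_theta)
    log_lik = log_likelihood_fast(params, arrays, **model_options)
    return FitResult(
        model_name=model_name,
        params=params,
        log_lik=log_lik,
        log_post=-float(best_fun),
        n_restarts_used=n_restarts,
        n_converged=int(n_converged),
        subject_id=subject_id,
        options=dict(model_options),
    )


# ---------------------------------------------------------------------------
# Laplace approximation
# ---------------------------------------------------------------------------

def hessian_central(
    fun: Callable[[np.ndarray], float],
    x: np.ndarray,
    rel_step: float = 1e-3,
) -> np.ndarray:
    """Hessian of ``fun`` at ``x`` by central finite differences.

    Per-parameter step ``rel_step * max(|x_i|, 1e-2)`` — the floor keeps
    the stencil wide enough to beat round-off when a parameter sits close
    to zero.
    """
    x = np.asarray(x, dtype=float)
    k = len(x)
    h = rel_step * np.maximum(np.abs(x), 1e-2)
    hess = np.empty((k, k))
    # inf - inf at support edges gives nan; callers treat non-finite entries
    # as a failed Hessian and retry with a larger step
    with np.errstate(invalid="ignore", over="ignore"):
        f0 = fun(x)
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = h[i]
            hess[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / h[i] ** 2
            for j in range(i + 1, k):
                ej = np.zeros(k)
                ej[j] = h[j]
                hess[i, j] = hess[j, i] = (
                    fun(x + ei + ej)
                    - fun(x + ei - ej)
                    - fun(x - ei + ej)
                    + fun(x - ei - ej)
                ) / (4.0 * h[i] * h[j])
    return hess


def laplace_log_evidence_generic(
    neg_log_post: Callable[[np.ndarray], float],
    x_map: np.ndarray,
    rel_step: float = 1e-3,
    retry_step: float = 1e-2,
    bounds: Optional[Sequence[tuple[float, float]]] = None,
) -> tuple[float, bool]:
    """Laplace log evidence for an arbitrary negative-log-posterior.

    Returns ``(log_evidence, hessian_ok)``; on a Hessian that is not
    positive definite after one retry with a larger step, ``(nan, False)``.

    When ``bounds`` are given and the optimum is pinned to a support
    boundary (common for misspecified dynamic-learning-rate fits, where
    the associability step size collapses to zero), the curvature is
    evaluated at the point nudged two steps inside the support: the exact
    Hessian is undefined on the boundary and the nearby interior curvature
    is the usable surrogate. The log-posterior height is still taken at
    the true optimum.
    """
    x_map = np.asarray(x_map, dtype=float)
    k = len(x_map)
    log_post = -neg_log_post(x_map)
    for step in (rel_step, retry_step):
        x_eval = x_map.copy()
        if bounds is not None:
            h = step * np.maximum(np.abs(x_map), 1e-2)
            for i, (lo, hi) in enumerate(bounds):
                x_eval[i] = min(max(x_map[i], lo + 2 * h[i]), hi - 2 * h[i])
        hess = hessian_central(neg_log_post, x_eval, step)
        if not np.all(np.isfinite(hess)):
            continue
        try:
            chol = np.linalg.cholesky(hess)
        except np.linalg.LinAlgError:
            continue
        log_det = 2.0 * float(np.sum(np.log(np.diag(chol))))
        return log_post + 0.5 * k * LOG_2PI - 0.5 * log_det, True
    return math.nan, False


def laplace_evidence(
    fit: FitResult,
    trials: Sequence[TrialRecord],
    priors: PriorSpec | str = "default",
    rel_step: float = 1e-3,
    retry_step: float = 1e-2,
) -> FitResult:
    """Fill ``fit.log_evidence`` using the Laplace approximation at the MAP.

    The approximation requires an interior optimum: when the MAP is pinned
    to a prior-support boundary (within ``boundary_tol``), the Gaussian
    approximation is undefined there — its near-zero curvature direction
    would wildly overstate the evidence — so the evidence is left missing
    and the subject flagged. Likewise if the finite-difference Hessian is
    not positive definite after a retry with a larger step.
    """
    priors = get_priors(priors)
    objective = _make_neg_log_post(fit.model_name, trials, priors, fit.options)
    bounds = [priors[n].support for n in MODEL_FREE_PARAMS[fit.model_name]]
    boundary_tol = 1e-4
    for value, (lo, hi) in zip(fit.theta, bounds):
        if value - lo < boundary_tol or hi - value < boundary_tol:
            fit.log_evidence = None
            fit.hessian_ok = False
            return fit
    log_ev, ok = laplace_log_evidence_generic(
        objective, fit.theta, rel_step, retry_step, bounds
    )
    fit.log_evidence = log_ev if ok else None
    fit.hessian_ok = ok
    return fit


def fit_subject(
    model_name: str,
    trials: Sequence[TrialRecord],
    priors: PriorSpec | str = "default",
    n_restarts: int = 100,
    seed: Optional[int] = None,
    **kwargs,
) -> FitResult:
    """MAP fit plus Laplace evidence in one call."""
    fit = fit_map(model_name, trials, priors, n_restarts, seed, **kwargs)
    return laplace_evidence(fit, trials, priors)


def fits_to_frame(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Tidy table of fits: one row per subject x model."""
    all_params = sorted({p for ps in MODEL_FREE_PARAMS.values() for p in ps})
    rows = []
    for f in fits:
        row = {
            "subject_id": f.subject_id,
            "model": f.model_name,
            **{p: getattr(f.params, p) for p in all_params},
            "log_lik": f.log_lik,
            "log_post": f.log_post,
            "log_evidence": np.nan if f.log_evidence is None else f.log_evidence,
            "hessian_ok": bool(f.hessian_ok),
            "n_restarts": f.n_restarts_used,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def compare_models(
    fits: pd.DataFrame | Sequence[FitResult],
    max_missing_fraction: float = 0.10,
) -> pd.DataFrame:
    """Mean Laplace evidence per model across subjects; best model flagged.

    Means are taken over complete cases — subjects with a valid evidence
    for every fitted model — so every model is averaged over the same
    subjects (averaging each model over its own valid subset would bias
    the comparison toward models whose hard-to-fit subjects were flagged).
    Ties in mean evidence break toward the model with fewer free
    parameters. Raises :class:`ComparisonError` when more than
    ``max_missing_fraction`` of subject x model evidences are missing.
    """
    if not isinstance(fits, pd.DataFrame):
        fits = fits_to_frame(fits)
    required = [m for m in MODEL_NAMES if m in set(fits["model"])]
    if not required:
        raise ComparisonError("no fitted models to compare")
    missing = fits["log_evidence"].isna().mean()
    if missing > max_missing_fraction:
        raise ComparisonError(
            f"{missing:.0%} of subject x model evidences missing "
            f"(limit {max_missing_fraction:.0%})"
        )
    wide = fits.pivot(index="subject_id", columns="model", values="log_evidence")
    complete = wide.dropna()
    if complete.empty:
        raise ComparisonError("no subject has a valid evidence for every model")
    table = (
        complete.mean()
        .rename("mean_evidence")
        .rename_axis("model")
        .reset_index()
    )
    table["n_subjects"] = len(complete)
    table["n_params"] = table["model"].map(lambda m: len(MODEL_FREE_PARAMS[m]))
    table["free_parameters"] = table["model"].map(
        lambda m: ", ".join(MODEL_FREE_PARAMS[m])
    )
    table = table.sort_values(
        ["mean_evidence", "n_params"], ascending=[False, True]
    ).reset_index(drop=True)
    table["winner"] = False
    table.loc[0, "winner"] = True
    return table[
        ["model", "free_parameters", "n_params", "n_subjects", "mean_evidence", "winner"]
    ]
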