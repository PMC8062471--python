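"""Reinforcement-learning models of probability learning with optional
probability weighting.

Eight models, each both a forward simulator (agent policy) and a trial-level
likelihood evaluator:

====== ==================================================================
name   description (free parameters)
====== ==================================================================
s1     Rescorla-Wagner, one learning rate (alpha, beta)
s2     asymmetric rates for positive/negative prediction errors
       (alpha_pos, alpha_neg, beta)
d1     Pearce-Hall associability-gated dynamic learning rate
       (mu, kappa, beta)
d2     split-half rates: one for the first half of trials, one for the
       second (alpha1, alpha2, beta)
s1w..  the same four models with a linear probability-weighting
d2w    parameter gamma added before beta
====== ==================================================================

All models learn the predicted reward probability ``p_t(A)`` of one option
(the other is its complement), initialized to 0.5. Expected values are
``Q_t = magnitude x p_t`` (or ``magnitude x F(p_t, gamma)`` for the
weighted variants) and choices follow a sigmoid in ``beta (Q_A - Q_B)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .task import (
    OPTION_A,
    OPTION_B,
    InputError,
    TaskConfig,
    TrialRecord,
    apply_magnitude_adjustment,
    build_schedule,
    resolve_trial,
)

MODEL_NAMES = ("s1", "s2", "d1", "d2", "s1w", "s2w", "d1w", "d2w")

#: Free parameters of each model, in canonical order.
MODEL_FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "s1": ("alpha", "beta"),
    "s2": ("alpha_pos", "alpha_neg", "beta"),
    "d1": ("mu", "kappa", "beta"),
    "d2": ("alpha1", "alpha2", "beta"),
    "s1w": ("alpha", "gamma", "beta"),
    "s2w": ("alpha_pos", "alpha_neg", "gamma", "beta"),
    "d1w": ("mu", "kappa", "gamma", "beta"),
    "d2w": ("alpha1", "alpha2", "gamma", "beta"),
}

#: Open support of each parameter (lower, upper), bounds excluded except
#: beta's lower bound (beta = 0 is a valid random-choice agent).
PARAM_SUPPORT: dict[str, tuple[float, float]] = {
    "alpha": (0.0, 1.0),
    "alpha_pos": (0.0, 1.0),
    "alpha_neg": (0.0, 1.0),
    "alpha1": (0.0, 1.0),
    "alpha2": (0.0, 1.0),
    "mu": (0.0, 1.0),
    "kappa": (0.0, math.inf),
    "gamma": (0.0, math.inf),
    "beta": (0.0, math.inf),
}


class ParameterError(ValueError):
    """A model parameter lies outside its support or is missing."""


@dataclass
class AgentParams:
    """Free parameters of one model; only the model's own fields are set."""

    model_name: str
    alpha: Optional[float] = None
    alpha_pos: Optional[float] = None
    alpha_neg: Optional[float] = None
    alpha1: Optional[float] = None
    alpha2: Optional[float] = None
    mu: Optional[float] = None
    kappa: Optional[float] = None
    gamma: Optional[float] = None
    beta: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model_name not in MODEL_FREE_PARAMS:
            raise ParameterError(f"unknown model {self.model_name!r}")
        for name in MODEL_FREE_PARAMS[self.model_name]:
            value = getattr(self, name)
            if value is None:
                raise ParameterError(f"{self.model_name} requires parameter {name}")
            lo, hi = PARAM_SUPPORT[name]
            ok = (lo <= value if name == "beta" else lo < value) and value < hi
            if not ok:
                raise ParameterError(
                    f"{name}={value} outside support ({lo}, {hi}) for "
                    f"model {self.model_name}"
                )

    @property
    def free_names(self) -> tuple[str, ...]:
        return MODEL_FREE_PARAMS[self.model_name]

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.free_names], dtype=float)

    @classmethod
    def from_vector(cls, model_name: str, theta: Sequence[float]) -> "AgentParams":
        names = MODEL_FREE_PARAMS[model_name]
        if len(theta) != len(names):
            raise ParameterError(
                f"{model_name} takes {len(names)} parameters, got {len(theta)}"
            )
        return cls(model_name, **dict(zip(names, map(float, theta))))


@dataclass
class LatentTrace:
    """Per-trial model internals, aligned with the trial log.

    ``p_pred`` is the predicted probability of option A at decision time
    (before the trial's update); ``delta``/``alpha_t`` are NaN on
    no-response trials, ``S``/``alpha_t`` are NaN for models without an
    associability state where not applicable.
    """

    p_pred: np.ndarray
    delta: np.ndarray
    S: np.ndarray
    alpha_t: np.ndarray
    q_A: np.ndarray
    q_B: np.ndarray
    p_choice_A: np.ndarray
    model_name: str = ""

    def to_frame(self, subject_id: Optional[str] = None) -> pd.DataFrame:
        n = len(self.p_pred)
        frame = pd.DataFrame(
            {
                "trial": np.arange(1, n + 1),
                "p_pred": self.p_pred,
                "delta": self.delta,
                "S": self.S,
                "alpha_t": self.alpha_t,
                "q_A": self.q_A,
                "q_B": self.q_B,
                "p_choice_A": self.p_choice_A,
            }
        )
        frame.insert(0, "model", self.model_name)
        if subject_id is not None:
            frame.insert(0, "subject_id", subject_id)
        return frame


# ---------------------------------------------------------------------------
# Elementary update rules
# ---------------------------------------------------------------------------

def update_static(p_pred: float, r: int, alpha: float) -> tuple[float, float]:
    """One Rescorla-Wagner step: p <- p + alpha * (r - p)."""
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")
    delta = r - p_pred
    return p_pred + alpha * delta, delta


def update_asymmetric(
    p_pred: float, r: int, alpha_pos: float, alpha_neg: float
) -> tuple[float, float]:
    """Rescorla-Wagner step with separate rates for +/- prediction errors."""
    if not (0.0 < alpha_pos < 1.0 and 0.0 < alpha_neg < 1.0):
        raise ParameterError("alpha_pos and alpha_neg must lie in (0, 1)")
    delta = r - p_pred
    alpha = alpha_pos if delta > 0 else alpha_neg if delta < 0 else alpha_pos
    return p_pred + alpha * delta, delta


def update_pearce_hall(
    p_pred: float, r: int, S: float, mu: float, kappa: float
) -> tuple[float, float, float, float]:
    """Pearce-Hall step: associability tracks recent |prediction error|.

    The associability is updated with the current trial's |delta| first,
    and the resulting rate ``alpha_t = min(kappa * S_new, 1)`` is applied to
    this trial's value update.

    Returns ``(new_p_pred, new_S, alpha_t, delta)``.
    """
    if S < 0:
        raise ParameterError(f"associability must be >= 0, got {S}")
    if not 0.0 < mu < 1.0:
        raise ParameterError(f"mu must lie in (0, 1), got {mu}")
    if kappa <= 0:
        raise ParameterError(f"kappa must be > 0, got {kappa}")
    delta = r - p_pred
    new_s = (1.0 - mu) * S + mu * abs(delta)
    alpha_t = min(kappa * new_s, 1.0)
    return p_pred + alpha_t * delta, new_s, alpha_t, delta


def update_split_half(
    p_pred: float,
    r: int,
    trial_index: int,
    n_trials: int,
    alpha1: float,
    alpha2: float,
) -> tuple[float, float]:
    """Rescorla-Wagner step with one rate per half of the session."""
    if not 1 <= trial_index <= n_trials:
        raise InputError(
            f"trial_index {trial_index} outside 1..{n_trials}"
        )
    alpha = alpha1 if trial_index <= n_trials / 2 else alpha2
    return update_static(p_pred, r, alpha)


def weight_probability(p_pred: float, gamma: float) -> float:
    """Linear probability weighting around 0.5, clipped to [0, 1].

    ``gamma = 1`` is the identity (risk-neutral); ``gamma > 1`` compresses
    probabilities toward 0/1 (risk-aversive), ``gamma < 1`` flattens them
    toward 0.5 (risk-seeking).
    """
    if gamma <= 0:
        raise ParameterError(f"gamma must be > 0, got {gamma}")
    return min(max(gamma * (p_pred - 0.5) + 0.5, 0.0), 1.0)


def choice_probability(q_a: float, q_b: float, beta: float) -> float:
    """Sigmoidal choice rule: P(A) = 1 / (1 + exp(-beta (Q_A - Q_B)))."""
    x = beta * (q_a - q_b)
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


# ---------------------------------------------------------------------------
# Stateful stepping shared by run_model and simulate_agent
# ---------------------------------------------------------------------------

P_INIT = 0.5  # predicted probability at the start of learning
S_INIT = 1.0  # Pearce-Hall initial associability


class ModelState:
    """Latent learning state of one agent, stepped trial by trial."""

    def __init__(
        self,
        params: AgentParams,
        n_trials: int,
        *,
        s0: float = S_INIT,
        associability_first: bool = True,
    ) -> None:
        self.params = params
        self.base = params.model_name.rstrip("w")
        self.weighted = params.model_name.endswith("w")
        self.n_trials = n_trials
        self.s0 = s0
        self.associability_first = associability_first
        self.reset()

    def reset(self) -> None:
        """Re-initialize learned probability (and associability)."""
        self.p_a = P_INIT
        self.S = self.s0 if self.base == "d1" else math.nan
        self.last_alpha = math.nan

    def weighted_p(self, option: str) -> float:
        p = self.p_a if option == OPTION_A else 1.0 - self.p_a
        if self.weighted:
            return weight_probability(p, self.params.gamma)
        return p

    def q_values(self, mag_a: float, mag_b: float) -> tuple[float, float]:
        return mag_a * self.weighted_p(OPTION_A), mag_b * self.weighted_p(OPTION_B)

    def p_choose_a(self, mag_a: float, mag_b: float) -> float:
        q_a, q_b = self.q_values(mag_a, mag_b)
        return choice_probability(q_a, q_b, self.params.beta)

    def update(self, chosen: str, r: int, trial_index: int) -> float:
        """Apply the model's learning rule for the chosen option's outcome.

        Returns the prediction error delta for the chosen option.
        """
        p = self.params
        p_c = self.p_a if chosen == OPTION_A else 1.0 - self.p_a
        if self.base == "s1":
            new_p, delta = update_static(p_c, r, p.alpha)
            self.last_alpha = p.alpha
        elif self.base == "s2":
            new_p, delta = update_asymmetric(p_c, r, p.alpha_pos, p.alpha_neg)
            d0 = r - p_c
            self.last_alpha = p.alpha_pos if d0 > 0 else p.alpha_neg if d0 < 0 else p.alpha_pos
        elif self.base == "d2":
            new_p, delta = update_split_half(
                p_c, r, trial_index, self.n_trials, p.alpha1, p.alpha2
            )
            self.last_alpha = p.alpha1 if trial_index <= self.n_trials / 2 else p.alpha2
        else:  # d1, Pearce-Hall
            if self.associability_first:
                new_p, self.S, alpha_t, delta = update_pearce_hall(
                    p_c, r, self.S, p.mu, p.kappa
                )
            else:
                delta = r - p_c
                alpha_t = min(p.kappa * self.S, 1.0)
                new_p = p_c + alpha_t * delta
                self.S = (1.0 - p.mu) * self.S + p.mu * abs(delta)
            self.last_alpha = alpha_t
        self.p_a = new_p if chosen == OPTION_A else 1.0 - new_p
        return delta


# ---------------------------------------------------------------------------
# Whole-session evaluation and simulation
# ---------------------------------------------------------------------------

def run_model(
    params: AgentParams,
    trials: Sequence[TrialRecord],
    *,
    reset_at_block: bool = True,
    s0: float = S_INIT,
    associability_first: bool = True,
) -> tuple[LatentTrace, float]:
    """Evaluate a model on a completed trial log.

    For each responded trial the model computes both options' expected
    values, the sigmoidal probability of the observed choice, and
    accumulates its log; it then updates the learned probability from the
    chosen option's reward indicator. No-response trials contribute no
    likelihood and trigger no update. With ``reset_at_block`` the learned
    probability (and associability) re-initializes at each block boundary,
    mirroring the re-randomized contingency.

    Returns the per-trial :class:`LatentTrace` and the summed
    log-likelihood.
    """
    if len(trials) == 0:
        raise InputError("empty trial list")
    n = len(trials)
    state = ModelState(
        params, n, s0=s0, associability_first=associability_first
    )
    tr = LatentTrace(
        *(np.full(n, np.nan) for _ in range(7)), model_name=params.model_name
    )
    log_lik = 0.0
    current_block = trials[0].block_index
    for i, rec in enumerate(trials):
        if reset_at_block and rec.block_index != current_block:
            current_block = rec.block_index
            state.reset()
        tr.p_pred[i] = state.p_a
        q_a, q_b = state.q_values(rec.magnitude_A, rec.magnitude_B)
        tr.q_A[i], tr.q_B[i] = q_a, q_b
        p_a = choice_probability(q_a, q_b, params.beta)
        tr.p_choice_A[i] = p_a
        tr.S[i] = state.S
        if not rec.response_made or rec.chosen is None:
            continue
        p_obs = p_a if rec.chosen == OPTION_A else 1.0 - p_a
        log_lik += math.log(p_obs) if p_obs > 0 else -math.inf
        r = 1 if rec.chosen == rec.rewarded else 0
        delta = state.update(rec.chosen, r, rec.trial_index)
        tr.delta[i] = delta
        tr.alpha_t[i] = state.last_alpha
        if state.base == "d1":
            tr.S[i] = state.S
    return tr, log_lik


def trials_to_arrays(trials: Sequence[TrialRecord]) -> dict[str, np.ndarray]:
    """Pack a trial log into flat arrays for the fast likelihood kernel."""
    n = len(trials)
    chosen = np.full(n, -1, dtype=np.int64)
    reward = np.zeros(n, dtype=np.int64)
    responded = np.zeros(n, dtype=np.bool_)
    mag_a = np.empty(n)
    mag_b = np.empty(n)
    block = np.empty(n, dtype=np.int64)
    tidx = np.empty(n, dtype=np.int64)
    for i, rec in enumerate(trials):
        mag_a[i] = rec.magnitude_A
        mag_b[i] = rec.magnitude_B
        block[i] = rec.block_index
        tidx[i] = rec.trial_index
        if rec.response_made and rec.chosen is not None:
            chosen[i] = 0 if rec.chosen == OPTION_A else 1
            responded[i] = True
            reward[i] = 1 if rec.chosen == rec.rewarded else 0
    return {
        "chosen": chosen,
        "reward": reward,
        "responded": responded,
        "mag_a": mag_a,
        "mag_b": mag_b,
        "block": block,
        "tidx": tidx,
    }


def log_likelihood_fast(
    params: AgentParams,
    arrays: dict[str, np.ndarray],
    *,
    reset_at_block: bool = True,
    s0: float = S_INIT,
    associability_first: bool = True,
) -> float:
    """Compiled-path log-likelihood; agrees with :func:`run_model` to 1e-10."""
    base, weighted, a1, a2, gamma, beta = _kernels.encode(params)
    return _kernels.loglik(
        base,
        weighted,
        a1,
        a2,
        gamma,
        beta,
        arrays["chosen"],
        arrays["reward"],
        arrays["responded"],
        arrays["mag_a"],
        arrays["mag_b"],
        arrays["block"],
        arrays["tidx"],
        int(arrays["tidx"][-1]),
        reset_at_block,
        s0,
        associability_first,
    )


def simulate_agent(
    params: AgentParams,
    config: TaskConfig,
    seed: Optional[int] = None,
    *,
    rng: Optional[np.random.Generator] = None,
    reset_at_block: bool = True,
    s0: float = S_INIT,
    associability_first: bool = True,
) -> list[TrialRecord]:
    """Simulate one agent through a full task session.

    Draws a fresh schedule, samples each choice from the model's sigmoidal
    choice rule, applies the repeat-choice magnitude adjustment, and
    resolves outcomes, returning a completed trial log ready for fitting.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    schedule = build_schedule(config, rng)
    state = ModelState(
        params, config.n_trials, s0=s0, associability_first=associability_first
    )
    out: list[TrialRecord] = []
    block_choices: list[Optional[str]] = []
    current_block = 1
    for rec in schedule:
        if rec.block_index != current_block:
            current_block = rec.block_index
            block_choices = []
            if reset_at_block:
                state.reset()
        rec = apply_magnitude_adjustment(block_choices, rec, config, rng)
        p_a = state.p_choose_a(rec.magnitude_A, rec.magnitude_B)
        choice = OPTION_A if rng.random() < p_a else OPTION_B
        rec = resolve_trial(rec, choice)
        block_choices.append(choice)
        r = 1 if choice == rec.rewarded else 0
        state.update(choice, r, rec.trial_index)
        out.append(rec)
    return out
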