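"""Prior distributions for MAP estimation.

Defaults: learning rates (alpha, alpha+, alpha-, alpha1, alpha2) carry a
Beta(4.6, 50) prior, the probability-weighting slope gamma a Gamma(1.9,
scale=1.0) prior, the inverse temperature beta a Gamma(2.8, scale=0.05)
prior, and the Pearce-Hall parameters kappa and mu an uninformative
Beta(1, 1). Gamma distributions use the shape-scale parameterization, so
the beta prior has mean 0.14 — a typical inverse temperature when expected
values live on a 0-100 point scale.

Log-densities are evaluated in plain ``math`` (they sit inside the
optimizer's inner loop); tests check them against ``scipy.stats``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .models import MODEL_FREE_PARAMS


@dataclass(frozen=True)
class BetaPrior:
    """Beta(a, b) on (0, 1)."""

    a: float
    b: float

    def logpdf(self, x: float) -> float:
        if not 0.0 < x < 1.0:
            return -math.inf
        log_b = math.lgamma(self.a) + math.lgamma(self.b) - math.lgamma(self.a + self.b)
        return (self.a - 1.0) * math.log(x) + (self.b - 1.0) * math.log1p(-x) - log_b

    def sample(self, rng: np.random.Generator, size=None):
        return rng.beta(self.a, self.b, size=size)

    def frozen(self):
        return stats.beta(self.a, self.b)

    @property
    def support(self) -> tuple[float, float]:
        return (0.0, 1.0)


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(shape, scale) on (0, inf)."""

    shape: float
    scale: float

    def logpdf(self, x: float) -> float:
        if x <= 0.0:
            return -math.inf
        k, th = self.shape, self.scale
        return (k - 1.0) * math.log(x) - x / th - math.lgamma(k) - k * math.log(th)

    def sample(self, rng: np.random.Generator, size=None):
        return rng.gamma(self.shape, self.scale, size=size)

    def frozen(self):
        return stats.gamma(self.shape, scale=self.scale)

    @property
    def support(self) -> tuple[float, float]:
        return (0.0, math.inf)


Prior = BetaPrior | GammaPrior
PriorSpec = Mapping[str, Prior]

_RATE_NAMES = ("alpha", "alpha_pos", "alpha_neg", "alpha1", "alpha2")


def default_priors(rate_prior: BetaPrior = BetaPrior(4.6, 50.0)) -> dict[str, Prior]:
    """The default prior set (see module docstring)."""
    priors: dict[str, Prior] = {name: rate_prior for name in _RATE_NAMES}
    priors["gamma"] = GammaPrior(1.9, 1.0)
    priors["beta"] = GammaPrior(2.8, 0.05)
    priors["mu"] = BetaPrior(1.0, 1.0)
    priors["kappa"] = BetaPrior(1.0, 1.0)
    return priors


#: Named prior sets. "default" follows the study; "flat_rates" swaps the
#: learning-rate prior for the less constrained Beta(2, 2) used in
#: sensitivity analyses.
PRIOR_SETS: dict[str, dict[str, Prior]] = {
    "default": default_priors(),
    "flat_rates": default_priors(rate_prior=BetaPrior(2.0, 2.0)),
}


def get_priors(name_or_spec: str | PriorSpec = "default") -> PriorSpec:
    if isinstance(name_or_spec, str):
        try:
            return PRIOR_SETS[name_or_spec]
        except KeyError:
            raise KeyError(
                f"unknown prior set {name_or_spec!r}; "
                f"available: {sorted(PRIOR_SETS)}"
            ) from None
    return name_or_spec


def check_coverage(model_name: str, priors: PriorSpec) -> None:
    """Raise if any free parameter of the model lacks a prior."""
    missing = [n for n in MODEL_FREE_PARAMS[model_name] if n not in priors]
    if missing:
        raise KeyError(f"priors missing for {model_name} parameters: {missing}")
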