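"""Two-option probabilistic reward task.

Simulates the 60-trial task in which two fractal stimuli carry complementary
reward magnitudes (R and 100-R points) and fixed but hidden reward
probabilities (0.75 vs 0.25). The contingency is re-randomized every 20
trials, giving three blocks. On every trial exactly one stimulus is rewarded;
choosing it earns its displayed magnitude. A magnitude adjustment discourages
perseveration: once the same stimulus has been chosen twice in a row, its
magnitude on the next trial is redrawn from the lower half of the range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

OPTION_A = "A"
OPTION_B = "B"
OPTIONS = (OPTION_A, OPTION_B)


class ConfigurationError(ValueError):
    """A task or run configuration violates one of its invariants."""


class InputError(ValueError):
    """A runtime input (choice, record, index) is invalid."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the probabilistic two-option reward task.

    Defaults reproduce the study task: 60 trials in blocks of 20, a 0.75/0.25
    reward contingency, and integer magnitudes R and ``magnitude_total - R``
    with R uniform on 1..99.
    """

    n_trials: int = 60
    block_length: int = 20
    p_high: float = 0.75
    magnitude_low: int = 1
    magnitude_high: int = 99
    magnitude_total: int = 100
    adjustment_enabled: bool = True
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.block_length <= 0 or self.n_trials <= 0:
            raise ConfigurationError("n_trials and block_length must be positive")
        if self.n_trials % self.block_length != 0:
            raise ConfigurationError(
                f"n_trials ({self.n_trials}) must be a multiple of "
                f"block_length ({self.block_length})"
            )
        if not 0.5 < self.p_high < 1.0:
            raise ConfigurationError(f"p_high must lie in (0.5, 1), got {self.p_high}")
        if self.magnitude_low < 1:
            raise ConfigurationError("magnitude_low must be >= 1")
        if self.magnitude_high != self.magnitude_total - self.magnitude_low:
            raise ConfigurationError(
                "magnitude_high must equal magnitude_total - magnitude_low"
            )

    @property
    def n_blocks(self) -> int:
        return self.n_trials // self.block_length


@dataclass
class TrialRecord:
    """One trial of the task, before or after the choice is resolved.

    ``chosen`` is ``None`` until :func:`resolve_trial` runs; a no-response
    trial keeps ``chosen=None`` with ``response_made=False``.
    """

    trial_index: int  # 1-based
    block_index: int  # 1-based
    high_prob_option: str
    magnitude_A: int
    magnitude_B: int
    rewarded: str
    chosen: Optional[str] = None
    response_made: bool = False
    adjusted: bool = field(default=False, repr=False)

    @property
    def points_earned(self) -> int:
        if not self.response_made or self.chosen != self.rewarded:
            return 0
        return self.magnitude_A if self.chosen == OPTION_A else self.magnitude_B

    def magnitude(self, option: str) -> int:
        return self.magnitude_A if option == OPTION_A else self.magnitude_B


def _draw_magnitudes(config: TaskConfig, rng: np.random.Generator) -> tuple[int, int]:
    r = int(rng.integers(config.magnitude_low, config.magnitude_high + 1))
    return r, config.magnitude_total - r


def build_schedule(
    config: TaskConfig, rng: Optional[np.random.Generator] = None
) -> list[TrialRecord]:
    """Pre-draw a full trial schedule: contingencies, magnitudes and rewards.

    Within each block the identity of the high-probability option is constant
    and drawn uniformly at block start. The rewarded option is pre-drawn per
    trial with P(high option rewarded) = ``p_high``, independent of any later
    choice. Magnitudes are complementary integers.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    records: list[TrialRecord] = []
    for t in range(1, config.n_trials + 1):
        block = 1 + (t - 1) // config.block_length
        if (t - 1) % config.block_length == 0:
            high = OPTIONS[int(rng.integers(2))]
        mag_a, mag_b = _draw_magnitudes(config, rng)
        if rng.random() < config.p_high:
            rewarded = high
        else:
            rewarded = OPTION_B if high == OPTION_A else OPTION_A
        records.append(
            TrialRecord(
                trial_index=t,
                block_index=block,
                high_prob_option=high,
                magnitude_A=mag_a,
                magnitude_B=mag_b,
                rewarded=rewarded,
            )
        )
    return records


def apply_magnitude_adjustment(
    history: Sequence[Optional[str]],
    record: TrialRecord,
    config: TaskConfig,
    rng: np.random.Generator,
) -> TrialRecord:
    """Redraw the over-chosen option's magnitude from the lower half.

    ``history`` holds the choices made so far in the current block (``None``
    for a no-response trial). If its last two entries name the same option,
    that option's magnitude is redrawn uniformly from
    ``{magnitude_low, ..., floor(magnitude_total/2) - 1}`` and the other
    option receives the complement; otherwise the record is returned
    unchanged. A no-response trial breaks the run, as does a block boundary
    (the caller passes per-block history).
    """
    if not config.adjustment_enabled or len(history) < 2:
        return record
    last, prev = history[-1], history[-2]
    if last is None or last != prev:
        return record
    upper = config.magnitude_total // 2 - 1
    r = int(rng.integers(config.magnitude_low, upper + 1))
    out = replace(record, adjusted=True)
    if last == OPTION_A:
        out.magnitude_A, out.magnitude_B = r, config.magnitude_total - r
    else:
        out.magnitude_B, out.magnitude_A = r, config.magnitude_total - r
    return out


def resolve_trial(record: TrialRecord, choice: Optional[str]) -> TrialRecord:
    """Complete a trial with the agent's (or subject's) choice.

    ``choice`` may be ``"A"``, ``"B"`` or ``None`` (no response). A
    no-response trial earns zero points and is excluded from likelihoods
    downstream.
    """
    if choice not in (OPTION_A, OPTION_B, None):
        raise InputError(f"choice must be 'A', 'B' or None, got {choice!r}")
    record.chosen = choice
    record.response_made = choice is not None
    return record


def expected_values(record: TrialRecord, config: TaskConfig) -> tuple[float, float]:
    """True expected value of each option: true probability x magnitude."""
    p_a = config.p_high if record.high_prob_option == OPTION_A else 1 - config.p_high
    return p_a * record.magnitude_A, (1 - p_a) * record.magnitude_B
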