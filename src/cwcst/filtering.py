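"""Participant validity screening and trial-level RT exclusions.

Two screens run before any reliability analysis:

1. **Cohort validity screen.** A participant's test performance is invalid
   when any category (color, shape, number, or the no-match key) was applied
   more or less often than the cohort mean application count of that
   category by more than ``validity_sd`` cohort standard deviations. The
   screen is a single pass: cohort means and SDs are computed once over all
   participants and not recomputed after exclusion.

2. **RT exclusions.** For RT analysis a trial is dropped when its RT is
   faster than ``rt_floor_ms`` (strictly below), slower than the
   participant's individual cut-off (individual mean RT plus
   ``rt_ceiling_sd`` individual SDs, computed over *all* experimental trials
   before any exclusion), or carries a PE, SLE, or IE.

Mean RTs are then computed per trial type over the surviving trials;
inference trials, being a sub-type of switch trials, contribute to both the
switch and the inference mean. Sample SDs (denominator ``n - 1``) are used
throughout, the convention in this literature; set ``ddof=0`` for population
SDs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scoring import ErrorFlags, TrialTypeLabels, category_application_counts
from .task import CATEGORY_NAMES, ParticipantLog

__all__ = [
    "FilterConfig",
    "ScreeningResult",
    "RTSummary",
    "screen_participants",
    "valid_rt_mask",
    "mean_rt_by_type",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the validity screen and the RT exclusions."""

    rt_floor_ms: float = 100.0
    rt_ceiling_sd: float = 3.0
    validity_sd: float = 3.0
    ddof: int = 1  # sample SD by default

    def __post_init__(self) -> None:
        if self.rt_floor_ms <= 0 or self.rt_ceiling_sd <= 0 or self.validity_sd <= 0:
            raise ValueError("all filter thresholds must be positive")
        if self.ddof not in (0, 1):
            raise ValueError("ddof must be 0 or 1")


@dataclass(frozen=True)
class ScreeningResult:
    """Outcome of the cohort validity screen."""

    participant_ids: tuple[str, ...]
    counts: np.ndarray  # (n_participants, 4) category application counts
    cohort_mean: np.ndarray  # (4,)
    cohort_sd: np.ndarray  # (4,)
    included: np.ndarray  # (n_participants,) bool
    reasons: tuple[str, ...]  # "" for included participants

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    @property
    def n_excluded(self) -> int:
        return int((~self.included).sum())


@dataclass(frozen=True)
class RTSummary:
    """Valid-trial counts and mean RTs per trial type for one participant.

    A type with zero valid trials has mean ``nan`` (undefined, never zero).
    """

    participant_id: str
    n_valid_switch: int
    n_valid_repeat: int
    n_valid_inference: int
    mean_rt_switch: float
    mean_rt_repeat: float
    mean_rt_inference: float


def screen_participants(
    cohort: list[ParticipantLog], config: FilterConfig | None = None
) -> ScreeningResult:
    """Flag participants whose category-application profile is an outlier.

    For each category the mean and SD of application counts are computed
    across the whole cohort; a participant is excluded iff the absolute
    deviation from the mean exceeds ``validity_sd`` SDs for *any* category
    (strict inequality). With fewer than two participants the SD is
    undefined and the screen raises.
    """
    if config is None:
        config = FilterConfig()
    if len(cohort) < 2:
        raise ValueError("validity screening needs a cohort of at least 2 participants")
    counts = np.stack([category_application_counts(log) for log in cohort])
    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=config.ddof)
    dev = np.abs(counts - mean)
    outlying = dev > config.validity_sd * sd  # sd == 0 -> nothing is outlying
    included = ~outlying.any(axis=1)
    reasons = tuple(
        ""
        if ok
        else "; ".join(
            f"{CATEGORY_NAMES[c]} applied {int(counts[i, c])}x "
            f"(cohort {mean[c]:.2f} ± {sd[c]:.2f})"
            for c in np.flatnonzero(row)
        )
        for i, (ok, row) in enumerate(zip(included, outlying))
    )
    return ScreeningResult(
        participant_ids=tuple(log.participant_id for log in cohort),
        counts=counts,
        cohort_mean=mean,
        cohort_sd=sd,
        included=included,
        reasons=reasons,
    )


def valid_rt_mask(
    log: ParticipantLog,
    labels: TrialTypeLabels,
    errors: ErrorFlags,
    config: FilterConfig | None = None,
) -> np.ndarray:
    """Boolean mask of experimental trials that enter RT analysis.

    A trial survives iff its RT is at least the floor (strictly-faster
    trials are dropped, an exact-floor RT stays), at most the individual
    mean + ``rt_ceiling_sd``·SD cut-off computed over all experimental trials
    before any exclusion, and carries no PE/SLE/IE.
    """
    if config is None:
        config = FilterConfig()
    rt = log.experimental.rt_ms
    if len(rt) < 2:
        raise ValueError("individual RT cut-off needs at least 2 trials")
    if len(labels) != len(rt):
        raise ValueError("labels do not align with the experimental block")
    cutoff = rt.mean() + config.rt_ceiling_sd * rt.std(ddof=config.ddof)
    return (rt >= config.rt_floor_ms) & (rt <= cutoff) & ~errors.any


def mean_rt_by_type(
    log: ParticipantLog, labels: TrialTypeLabels, mask: np.ndarray
) -> RTSummary:
    """Mean RT on switch, repeat, and inference trials over masked-in trials.

    Inference trials count toward both the switch and the inference mean.
    """
    rt = log.experimental.rt_ms
    mask = np.asarray(mask, dtype=bool)
    if len(mask) != len(rt):
        raise ValueError("mask does not align with the experimental block")

    n_sw = int((labels.is_switch & mask).sum())
    n_rp = int((labels.is_repeat & mask).sum())
    n_inf = int((labels.is_inference & mask).sum())
    return RTSummary(
        participant_id=log.participant_id,
        n_valid_switch=n_sw,
        n_valid_repeat=n_rp,
        n_valid_inference=n_inf,
        mean_rt_switch=float(rt[labels.is_switch & mask].mean()) if n_sw else float("nan"),
        mean_rt_repeat=float(rt[labels.is_repeat & mask].mean()) if n_rp else float("nan"),
        mean_rt_inference=float(rt[labels.is_inference & mask].mean()) if n_inf else float("nan"),
    )
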