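"""Trial-type classification and error scoring for cWCST logs.

Every experimental trial after the first is classified by the feedback on the
preceding trial: negative feedback makes it a *switch* trial (the sorting
category should change), positive feedback a *repeat* trial (the category
should be maintained). *Inference* trials are the sub-type of switch trials
on which the prevailing category is logically deducible: they follow a switch
trial on which the participant did switch the applied category and was again
wrong, so two of the three categories stand disconfirmed.

Three error scores are tallied per participant:

- **PE** (perseveration error): repeating the previously applied category on
  a switch trial;
- **SLE** (set-loss error): switching away from the previously applied
  category on a repeat trial;
- **IE** (inference error): applying any category other than the prevailing
  one on an inference trial.

The three definitions are independent predicates; in particular a
perseverative response on an inference trial increments both PE and IE. A
response on the no-match key ("other") counts as an SLE on repeat trials and
an IE on inference trials, but never as a PE — it repeats no category.
All scoring runs over the experimental block only and ignores response times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .task import COLOR, NUMBER, OTHER, SHAPE, ParticipantLog

__all__ = [
    "UNLABELED",
    "SWITCH",
    "REPEAT",
    "TrialTypeLabel",
    "TrialTypeLabels",
    "ErrorCounts",
    "ErrorFlags",
    "classify_trial_types",
    "error_flags",
    "score_errors",
    "category_application_counts",
]

UNLABELED, SWITCH, REPEAT = 0, 1, 2
_BASE_NAMES = {UNLABELED: "unlabeled", SWITCH: "switch", REPEAT: "repeat"}


@dataclass(frozen=True)
class TrialTypeLabel:
    """Label of one trial: base type plus the inference sub-type flag."""

    base: str  # "unlabeled" | "switch" | "repeat"
    is_inference: bool

    def __post_init__(self) -> None:
        if self.is_inference and self.base != "switch":
            raise ValueError("only switch trials can be inference trials")


class TrialTypeLabels:
    """Vectorized trial-type labels for one participant's experimental block.

    Behaves as a sequence of :class:`TrialTypeLabel`; the underlying arrays
    (``base`` with codes UNLABELED/SWITCH/REPEAT and boolean
    ``is_inference``) are what downstream code consumes.
    """

    __slots__ = ("base", "is_inference")

    def __init__(self, base: np.ndarray, is_inference: np.ndarray) -> None:
        self.base = np.asarray(base, dtype=np.int64)
        self.is_inference = np.asarray(is_inference, dtype=bool)
        if len(self.base) != len(self.is_inference):
            raise ValueError("label arrays must have equal length")
        if np.any(self.is_inference & (self.base != SWITCH)):
            raise ValueError("inference labels are only valid on switch trials")

    def __len__(self) -> int:
        return len(self.base)

    def __getitem__(self, i: int) -> TrialTypeLabel:
        return TrialTypeLabel(_BASE_NAMES[int(self.base[i])], bool(self.is_inference[i]))

    def __iter__(self) -> Iterator[TrialTypeLabel]:
        return (self[i] for i in range(len(self)))

    @property
    def is_switch(self) -> np.ndarray:
        return self.base == SWITCH

    @property
    def is_repeat(self) -> np.ndarray:
        return self.base == REPEAT


@dataclass(frozen=True)
class ErrorCounts:
    """Per-participant trial-type counts and error tallies."""

    participant_id: str
    n_trials: int
    n_switch: int
    n_repeat: int
    n_inference: int
    pe: int
    sle: int
    ie: int

    def __post_init__(self) -> None:
        if self.n_trials > 0 and self.n_switch + self.n_repeat != self.n_trials - 1:
            raise ValueError("switch + repeat trials must equal n_trials - 1")
        if not (
            self.n_inference <= self.n_switch
            and self.pe <= self.n_switch
            and self.sle <= self.n_repeat
            and self.ie <= self.n_inference
        ):
            raise ValueError("error tallies exceed their trial-type counts")


@dataclass(frozen=True)
class ErrorFlags:
    """Per-trial boolean error indicators over the experimental block."""

    pe: np.ndarray
    sle: np.ndarray
    ie: np.ndarray

    @property
    def any(self) -> np.ndarray:
        return self.pe | self.sle | self.ie


def classify_trial_types(log: ParticipantLog) -> TrialTypeLabels:
    """Label each experimental trial as unlabeled/switch/repeat (+ inference).

    Trial ``t`` (1-based, ``t >= 2``) is a switch trial iff feedback on
    ``t-1`` was negative, else a repeat trial; the first trial carries no
    preceding feedback and stays unlabeled. Trial ``t`` is an inference trial
    iff ``t-1`` was itself a switch trial on which the applied category
    changed relative to ``t-2`` and feedback on ``t-1`` was again negative.
    """
    exp = log.experimental
    n = len(exp)
    base = np.full(n, UNLABELED, dtype=np.int64)
    inference = np.zeros(n, dtype=bool)
    if n >= 2:
        prev_fb = exp.feedback[:-1]
        base[1:] = np.where(prev_fb, REPEAT, SWITCH)
    if n >= 3:
        prev_is_switch = base[1:-1] == SWITCH
        switched = exp.applied[1:-1] != exp.applied[:-2]
        prev_neg = ~exp.feedback[1:-1]
        inference[2:] = prev_is_switch & switched & prev_neg
    return TrialTypeLabels(base, inference)


def error_flags(log: ParticipantLog, labels: TrialTypeLabels) -> ErrorFlags:
    """Per-trial PE/SLE/IE indicators for the experimental block."""
    exp = log.experimental
    n = len(exp)
    if len(labels) != n:
        raise ValueError("labels do not align with the experimental block")
    pe = np.zeros(n, dtype=bool)
    sle = np.zeros(n, dtype=bool)
    ie = np.zeros(n, dtype=bool)
    if n >= 2:
        same_as_prev = exp.applied[1:] == exp.applied[:-1]
        # an "other" press repeats no category, so it is never a PE
        pe[1:] = labels.is_switch[1:] & same_as_prev & (exp.applied[1:] != OTHER)
        sle[1:] = labels.is_repeat[1:] & ~same_as_prev
    ie = labels.is_inference & (exp.applied != exp.prevailing)
    return ErrorFlags(pe=pe, sle=sle, ie=ie)


def score_errors(log: ParticipantLog, labels: TrialTypeLabels) -> ErrorCounts:
    """Tally trial types and PE/SLE/IE for one participant."""
    exp = log.experimental
    if len(labels) != len(exp):
        raise ValueError("labels do not align with the experimental block")
    flags = error_flags(log, labels)
    return ErrorCounts(
        participant_id=log.participant_id,
        n_trials=len(exp),
        n_switch=int(labels.is_switch.sum()),
        n_repeat=int(labels.is_repeat.sum()),
        n_inference=int(labels.is_inference.sum()),
        pe=int(flags.pe.sum()),
        sle=int(flags.sle.sum()),
        ie=int(flags.ie.sum()),
    )


def category_application_counts(log: ParticipantLog) -> np.ndarray:
    """How often each category (color, shape, number, other) was applied.

    Counts run over the experimental block and sum to its trial count; they
    feed the cohort-level validity screen.
    """
    exp = log.experimental
    counts = np.zeros(4, dtype=np.int64)
    for cat in (COLOR, SHAPE, NUMBER, OTHER):
        counts[cat] = int((exp.applied == cat).sum())
    return counts
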