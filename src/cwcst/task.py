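"""Core structure of the computerized Wisconsin Card Sorting Test (cWCST).

The task presents four fixed key cards — one red triangle, two green stars,
three yellow crosses, four blue circles — and a stream of stimulus cards that
must be sorted by color, shape, or number. The prevailing sorting category
switches covertly after a run of correct sorts, and the only signal of a
switch is negative feedback. This module defines the card space, the
feedback/category-inference logic, the switch schedule, and a session runner
that produces trial logs with the same shape as logs ingested from disk.

Category and card coding
------------------------
Sorting categories are small ints: ``COLOR=0, SHAPE=1, NUMBER=2``; ``OTHER=3``
marks a response whose chosen key card matches the stimulus on no dimension.
Colors and shapes are coded by the key-card position that carries them
(position 1 = red/triangle, 2 = green/star, 3 = yellow/cross, 4 =
blue/circle), so a stimulus card is a triple ``(number, color, shape)`` of
key-card positions. A card is unambiguous exactly when those three positions
are pairwise distinct: each category then maps to a distinct response key and
exactly one key card matches on no dimension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "COLOR",
    "SHAPE",
    "NUMBER",
    "OTHER",
    "CATEGORY_NAMES",
    "CATEGORY_CODES",
    "COLOR_NAMES",
    "SHAPE_NAMES",
    "KEY_CARDS",
    "VALID_STIMULI",
    "StimulusCard",
    "TaskConfig",
    "TrialRecord",
    "ParticipantLog",
    "generate_stimulus",
    "evaluate_response",
    "next_category_schedule",
    "run_session",
]

COLOR, SHAPE, NUMBER, OTHER = 0, 1, 2, 3

CATEGORY_NAMES = {COLOR: "color", SHAPE: "shape", NUMBER: "number", OTHER: "other"}
CATEGORY_CODES = {v: k for k, v in CATEGORY_NAMES.items()}

#: color / shape carried by each key-card position (1-based)
COLOR_NAMES = {1: "red", 2: "green", 3: "yellow", 4: "blue"}
SHAPE_NAMES = {1: "triangle", 2: "star", 3: "cross", 4: "circle"}
COLOR_CODES = {v: k for k, v in COLOR_NAMES.items()}
SHAPE_CODES = {v: k for k, v in SHAPE_NAMES.items()}

#: key card at position p shows p objects of color p and shape p (position coding)
KEY_CARDS = {p: (p, p, p) for p in (1, 2, 3, 4)}


@dataclass(frozen=True)
class StimulusCard:
    """An unambiguous stimulus card, coded by key-card positions.

    ``number`` is the object count (= position matched on number); ``color``
    and ``shape`` are the positions of the key cards sharing the stimulus
    color and shape. The three must be pairwise distinct.
    """

    number: int
    color: int
    shape: int

    def __post_init__(self) -> None:
        trio = (self.number, self.color, self.shape)
        if not all(v in (1, 2, 3, 4) for v in trio):
            raise ValueError(f"card attributes must be key positions 1-4, got {trio}")
        if len(set(trio)) != 3:
            raise ValueError(
                f"ambiguous stimulus card {trio}: the matched key-card positions "
                "must be pairwise distinct"
            )

    @property
    def color_name(self) -> str:
        return COLOR_NAMES[self.color]

    @property
    def shape_name(self) -> str:
        return SHAPE_NAMES[self.shape]


#: all 24 unambiguous cards, in a fixed order (deterministic sampling)
VALID_STIMULI: tuple[StimulusCard, ...] = tuple(
    StimulusCard(n, c, s) for n, c, s in permutations((1, 2, 3, 4), 3)
)
_STIM_INDEX = {(c.number, c.color, c.shape): i for i, c in enumerate(VALID_STIMULI)}


@dataclass(frozen=True)
class TaskConfig:
    """Structural parameters of a cWCST session.

    The prevailing category switches once a run of ``run length`` correct
    applications of that category is completed; run lengths are drawn
    uniformly from ``run_length_support`` (repeat an entry to weight it).
    The practice block ends after ``n_practice_switches`` switches, the
    experimental block after ``n_experimental_switches`` switches or when
    practice + experimental trials reach ``max_total_trials``. The timing
    fields are display metadata only, carried into logs but never used in
    any computation.
    """

    n_practice_switches: int = 6
    n_experimental_switches: int = 40
    max_total_trials: int = 250
    min_run_length: int = 2
    # Weighted toward short runs so that an error-free session ends after 40
    # switches in roughly 160 trials, the scale of a real session.
    run_length_support: tuple[int, ...] = (2, 2, 2, 3)
    categories: tuple[str, str, str] = ("color", "shape", "number")
    feedback_delay_ms: int = 500
    feedback_duration_ms: int = 300
    stimulus_delay_ms: int = 500

    def __post_init__(self) -> None:
        if self.min_run_length < 2:
            raise ValueError("min_run_length must be >= 2")
        if not self.run_length_support:
            raise ValueError("run_length_support must be non-empty")
        if any(r < self.min_run_length for r in self.run_length_support):
            raise ValueError("every run length must be >= min_run_length")
        if self.n_practice_switches < 0 or self.n_experimental_switches < 1:
            raise ValueError("switch counts invalid")
        if self.max_total_trials < 1:
            raise ValueError("max_total_trials must be positive")


@dataclass(frozen=True)
class TrialRecord:
    """One card sort: stimulus, response, category context, feedback, RT."""

    participant_id: str
    trial_index: int  # 1-based within block
    block: str  # "practice" | "experimental"
    stimulus: StimulusCard
    prevailing_category: int  # COLOR | SHAPE | NUMBER
    response: int  # key position 1-4
    applied_category: int  # COLOR | SHAPE | NUMBER | OTHER
    feedback: bool  # True = positive ("REPEAT"), False = negative ("SWITCH")
    rt_ms: float

    def __post_init__(self) -> None:
        applied, _ = evaluate_response(self.stimulus, self.response, self.prevailing_category)
        if applied != self.applied_category:
            raise ValueError(
                f"applied_category {self.applied_category} inconsistent with "
                f"stimulus/response (expected {applied})"
            )
        if self.feedback != (self.applied_category == self.prevailing_category):
            raise ValueError("feedback inconsistent with applied vs prevailing category")
        if self.rt_ms <= 0:
            raise ValueError("rt_ms must be positive")


class ParticipantLog:
    """Ordered trial log of one participant, stored column-wise.

    Columns are numpy arrays over all trials (practice first, then
    experimental). ``experimental`` views restrict to the experimental block,
    which is what every downstream analysis consumes.
    """

    __slots__ = (
        "participant_id",
        "is_practice",
        "trial_index",
        "stim_number",
        "stim_color",
        "stim_shape",
        "prevailing",
        "response",
        "applied",
        "feedback",
        "rt_ms",
    )

    def __init__(
        self,
        participant_id: str,
        *,
        is_practice: np.ndarray,
        trial_index: np.ndarray,
        stim_number: np.ndarray,
        stim_color: np.ndarray,
        stim_shape: np.ndarray,
        prevailing: np.ndarray,
        response: np.ndarray,
        applied: np.ndarray,
        feedback: np.ndarray,
        rt_ms: np.ndarray,
    ) -> None:
        self.participant_id = str(participant_id)
        self.is_practice = np.asarray(is_practice, dtype=bool)
        self.trial_index = np.asarray(trial_index, dtype=np.int64)
        self.stim_number = np.asarray(stim_number, dtype=np.int64)
        self.stim_color = np.asarray(stim_color, dtype=np.int64)
        self.stim_shape = np.asarray(stim_shape, dtype=np.int64)
        self.prevailing = np.asarray(prevailing, dtype=np.int64)
        self.response = np.asarray(response, dtype=np.int64)
        self.applied = np.asarray(applied, dtype=np.int64)
        self.feedback = np.asarray(feedback, dtype=bool)
        self.rt_ms = np.asarray(rt_ms, dtype=np.float64)
        n = len(self.trial_index)
        for name in self.__slots__[1:]:
            if len(getattr(self, name)) != n:
                raise ValueError("log columns must have equal length")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(cls, records: Sequence[TrialRecord]) -> "ParticipantLog":
        if not records:
            raise ValueError("cannot build a log from zero records")
        pid = records[0].participant_id
        if any(r.participant_id != pid for r in records):
            raise ValueError("records belong to different participants")
        return cls(
            pid,
            is_practice=np.array([r.block == "practice" for r in records]),
            trial_index=np.array([r.trial_index for r in records]),
            stim_number=np.array([r.stimulus.number for r in records]),
            stim_color=np.array([r.stimulus.color for r in records]),
            stim_shape=np.array([r.stimulus.shape for r in records]),
            prevailing=np.array([r.prevailing_category for r in records]),
            response=np.array([r.response for r in records]),
            applied=np.array([r.applied_category for r in records]),
            feedback=np.array([r.feedback for r in records]),
            rt_ms=np.array([r.rt_ms for r in records]),
        )

    def records(self) -> Iterator[TrialRecord]:
        for i in range(len(self)):
            yield TrialRecord(
                participant_id=self.participant_id,
                trial_index=int(self.trial_index[i]),
                block="practice" if self.is_practice[i] else "experimental",
                stimulus=StimulusCard(
                    int(self.stim_number[i]), int(self.stim_color[i]), int(self.stim_shape[i])
                ),
                prevailing_category=int(self.prevailing[i]),
                response=int(self.response[i]),
                applied_category=int(self.applied[i]),
                feedback=bool(self.feedback[i]),
                rt_ms=float(self.rt_ms[i]),
            )

    # -- views and checks ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.trial_index)

    @property
    def experimental(self) -> "ParticipantLog":
        """View restricted to the experimental block."""
        keep = ~self.is_practice
        if keep.all():
            return self
        return self._subset(keep)

    def _subset(self, keep: np.ndarray) -> "ParticipantLog":
        return ParticipantLog(
            self.participant_id,
            **{name: getattr(self, name)[keep] for name in self.__slots__[1:]},
        )

    @property
    def n_experimental(self) -> int:
        return int((~self.is_practice).sum())

    def validate(self) -> None:
        """Check log-level invariants; raise ``ValueError`` on the first breach."""
        if len(self) == 0:
            raise ValueError("empty log")
        if np.any(self.rt_ms <= 0):
            raise ValueError("rt_ms must be positive on every trial")
        trio = np.stack([self.stim_number, self.stim_color, self.stim_shape])
        if np.any((trio < 1) | (trio > 4)):
            raise ValueError("stimulus attributes must be key positions 1-4")
        if np.any(
            (self.stim_number == self.stim_color)
            | (self.stim_number == self.stim_shape)
            | (self.stim_color == self.stim_shape)
        ):
            raise ValueError("ambiguous stimulus card (matched positions not distinct)")
        # response -> applied category must be the unique matching dimension
        applied = np.full(len(self), OTHER, dtype=np.int64)
        applied[self.response == self.stim_color] = COLOR
        applied[self.response == self.stim_shape] = SHAPE
        applied[self.response == self.stim_number] = NUMBER
        if np.any(applied != self.applied):
            raise ValueError("applied_category inconsistent with stimulus/response")
        if np.any(self.feedback != (self.applied == self.prevailing)):
            raise ValueError("feedback inconsistent with applied vs prevailing category")
        if np.any(~self.is_practice[:-1] & self.is_practice[1:]):
            raise ValueError("practice trials must precede experimental trials")
        for block_mask in (self.is_practice, ~self.is_practice):
            idx = self.trial_index[block_mask]
            if len(idx) and np.any(idx != np.arange(1, len(idx) + 1)):
                raise ValueError("trial_index must be consecutive from 1 within a block")


# ---------------------------------------------------------------------------
# task logic
# ---------------------------------------------------------------------------


def generate_stimulus(
    rng: np.random.Generator, previous_stimulus: StimulusCard | None = None
) -> StimulusCard:
    """Draw an unambiguous stimulus card, distinct from the previous one.

    Cards are uniform over the 24 valid cards (those whose number, color and
    shape match three distinct key cards), excluding an exact repeat of
    ``previous_stimulus``.
    """
    if previous_stimulus is None:
        return VALID_STIMULI[int(rng.integers(len(VALID_STIMULI)))]
    prev = _STIM_INDEX[
        (previous_stimulus.number, previous_stimulus.color, previous_stimulus.shape)
    ]
    j = int(rng.integers(len(VALID_STIMULI) - 1))
    if j >= prev:
        j += 1
    return VALID_STIMULI[j]


def evaluate_response(
    stimulus: StimulusCard, response: int, prevailing: int
) -> tuple[int, bool]:
    """Map a key press to the applied category and the resulting feedback.

    The applied category is the unique dimension on which the chosen key card
    matches the stimulus, or ``OTHER`` if it matches on none. Feedback is
    positive iff the applied category is the prevailing one.
    """
    if response not in (1, 2, 3, 4):
        raise ValueError(f"response must be a key position 1-4, got {response}")
    if prevailing not in (COLOR, SHAPE, NUMBER):
        raise ValueError(f"prevailing must be color/shape/number, got {prevailing}")
    if response == stimulus.number:
        applied = NUMBER
    elif response == stimulus.color:
        applied = COLOR
    elif response == stimulus.shape:
        applied = SHAPE
    else:
        applied = OTHER
    return applied, applied == prevailing


def next_category_schedule(
    rng: np.random.Generator, config: TaskConfig, n_runs: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the hidden switch schedule for a block of ``n_runs`` runs.

    Returns ``(run_lengths, categories)``: each run requires ``run_lengths[i]``
    correct applications of ``categories[i]`` before the category switches.
    Run lengths are uniform over ``run_length_support``; the first category is
    uniform over the three categories and each successor is uniform over the
    two alternatives, so a successor never repeats its predecessor.
    """
    support = np.asarray(config.run_length_support, dtype=np.int64)
    lengths = support[rng.integers(len(support), size=n_runs)]
    cats = np.empty(n_runs, dtype=np.int64)
    cats[0] = rng.integers(3)
    # successor = uniform draw from the two categories != current
    steps = rng.integers(1, 3, size=max(n_runs - 1, 0))
    for i in range(1, n_runs):
        cats[i] = (cats[i - 1] + steps[i - 1]) % 3
    return lengths, cats


def run_session(agent, config: TaskConfig | None = None, rng=None) -> ParticipantLog:
    """Simulate one full session (practice + experimental block) of an agent.

    ``agent`` is any object exposing the behavioral-policy attributes of
    :class:`cwcst.simulate.AgentParams` (error probabilities, log-normal RT
    parameters, drift terms, participant_id). The session is a pure function
    of ``(agent, config, seed)``.

    The loop is written against flat pre-drawn random numbers and plain
    Python scalars: cohorts of hundreds of sessions are simulated thousands
    of times in the Monte-Carlo reliability oracle, so per-trial overhead
    dominates everything else in this package.
    """
    if config is None:
        config = TaskConfig()
    if rng is None:
        raise ValueError("run_session requires a seeded numpy Generator")

    max_trials = config.max_total_trials
    # hidden switch schedules for both blocks, drawn up front
    p_lengths, p_cats = next_category_schedule(rng, config, config.n_practice_switches or 1)
    e_lengths, e_cats = next_category_schedule(rng, config, config.n_experimental_switches)

    # pre-drawn randomness: 4 uniforms + 1 normal per potential trial
    u = rng.random(4 * max_trials).tolist()
    z = rng.standard_normal(max_trials).tolist()

    # agent policy parameters -> locals
    p_persev = float(agent.p_persev)
    p_setloss = float(agent.p_setloss)
    p_inferr = float(agent.p_inferr)
    p_other = float(agent.p_other)
    rt_loc = tuple(float(v) for v in agent.rt_location)  # (repeat, switch, inference)
    rt_scale = tuple(float(v) for v in agent.rt_scale)
    drift_error = float(agent.drift_error)
    drift_rt = float(agent.drift_rt)
    pid = str(getattr(agent, "participant_id", "sim"))

    exp_ = math.exp

    def _logit(p: float) -> float:
        if p <= 0.0:
            return -math.inf
        if p >= 1.0:
            return math.inf
        return math.log(p / (1.0 - p))

    lo_persev, lo_setloss, lo_inferr = _logit(p_persev), _logit(p_setloss), _logit(p_inferr)

    cols_practice: list[bool] = []
    cols_tidx: list[int] = []
    cols_n: list[int] = []
    cols_c: list[int] = []
    cols_s: list[int] = []
    cols_prev: list[int] = []
    cols_resp: list[int] = []
    cols_applied: list[int] = []
    cols_fb: list[bool] = []
    cols_rt: list[float] = []

    stimuli = VALID_STIMULI
    total = 0

    blocks = []
    if config.n_practice_switches > 0:
        blocks.append((True, p_lengths.tolist(), p_cats.tolist()))
    blocks.append((False, e_lengths.tolist(), e_cats.tolist()))

    for is_practice, lengths, cats in blocks:
        n_runs = len(lengths)
        run_idx = 0
        prevailing = cats[0]
        required = lengths[0]
        corrects = 0
        t_in_block = 0
        stim_idx = -1
        prev_applied = -1
        prev_feedback = True
        inference_ctx = False

        while total < max_trials:
            t_in_block += 1
            base = 4 * total
            # stimulus: uniform over valid cards, never an exact repeat
            if stim_idx < 0:
                stim_idx = int(u[base] * 24)
            else:
                j = int(u[base] * 23)
                if j >= stim_idx:
                    j += 1
                stim_idx = j
            card = stimuli[stim_idx]
            n_, c_, s_ = card.number, card.color, card.shape

            # drift shifts error log-odds linearly in the within-block index
            if drift_error != 0.0 and t_in_block > 1:
                shift = drift_error * (t_in_block - 1)
                pp = 1.0 / (1.0 + exp_(-(lo_persev + shift))) if 0.0 < p_persev < 1.0 else p_persev
                ps = 1.0 / (1.0 + exp_(-(lo_setloss + shift))) if 0.0 < p_setloss < 1.0 else p_setloss
                pi = 1.0 / (1.0 + exp_(-(lo_inferr + shift))) if 0.0 < p_inferr < 1.0 else p_inferr
            else:
                pp, ps, pi = p_persev, p_setloss, p_inferr

            # ---- behavioral policy: choose the category to apply ----
            if t_in_block == 1:
                applied = int(u[base + 1] * 3)  # no feedback context yet
                rt_ctx = 0
            elif prev_feedback:  # repeat context
                rt_ctx = 0
                if u[base + 1] < ps:  # set-loss lapse
                    if u[base + 3] < p_other:
                        applied = OTHER
                    else:
                        a = int(u[base + 2] * 2)  # one of the two other categories
                        applied = (prev_applied + 1 + a) % 3
                else:
                    applied = prev_applied
            else:  # switch context
                rt_ctx = 2 if inference_ctx else 1
                if u[base + 1] < pp:  # perseveration
                    applied = prev_applied
                elif inference_ctx:
                    if u[base + 2] < 1.0 - pi:
                        applied = prevailing
                    elif u[base + 3] < p_other:
                        applied = OTHER
                    elif prev_applied <= 2:
                        # the third category: neither just-disconfirmed nor prevailing
                        applied = 3 - prev_applied - prevailing
                    else:
                        # previous press matched no key dimension; err uniformly
                        # over the two non-prevailing categories (rescale the
                        # already-consumed uniform to stay unbiased)
                        v = (u[base + 2] - (1.0 - pi)) / pi
                        applied = (prevailing + 1 + int(v * 2)) % 3
                elif prev_applied <= 2:
                    applied = (prev_applied + 1 + int(u[base + 2] * 2)) % 3
                else:
                    applied = int(u[base + 2] * 3)

            if applied == OTHER:
                response = 10 - n_ - c_ - s_  # the key matching on no dimension
            elif applied == NUMBER:
                response = n_
            elif applied == COLOR:
                response = c_
            else:
                response = s_
            feedback = applied == prevailing

            rt = exp_(
                rt_loc[rt_ctx] + drift_rt * (t_in_block - 1) + rt_scale[rt_ctx] * z[total]
            )

            cols_practice.append(is_practice)
            cols_tidx.append(t_in_block)
            cols_n.append(n_)
            cols_c.append(c_)
            cols_s.append(s_)
            cols_prev.append(prevailing)
            cols_resp.append(response)
            cols_applied.append(applied)
            cols_fb.append(feedback)
            cols_rt.append(rt)
            total += 1

            # context the agent will see on the next trial
            cur_was_switch = (t_in_block > 1) and not prev_feedback
            inference_ctx = cur_was_switch and applied != prev_applied and not feedback
            prev_applied = applied
            prev_feedback = feedback

            # hidden run bookkeeping: errors neither advance nor reset the run
            if feedback:
                corrects += 1
                if corrects == required:
                    run_idx += 1
                    if run_idx == n_runs:
                        break  # block ends after its final switch
                    prevailing = cats[run_idx]
                    required = lengths[run_idx]
                    corrects = 0
        if total >= max_trials:
            break

    return ParticipantLog(
        pid,
        is_practice=np.array(cols_practice, dtype=bool),
        trial_index=np.array(cols_tidx, dtype=np.int64),
        stim_number=np.array(cols_n, dtype=np.int64),
        stim_color=np.array(cols_c, dtype=np.int64),
        stim_shape=np.array(cols_s, dtype=np.int64),
        prevailing=np.array(cols_prev, dtype=np.int64),
        response=np.array(cols_resp, dtype=np.int64),
        applied=np.array(cols_applied, dtype=np.int64),
        feedback=np.array(cols_fb, dtype=bool),
        rt_ms=np.array(cols_rt, dtype=np.float64),
    )
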