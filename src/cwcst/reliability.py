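"""Split-half reliability estimation with Spearman–Brown correction.

A test split assigns each of a participant's experimental trials to half A
or half B (balanced to within one trial). For a given performance measure —
an error count (PE, SLE, IE), a conditional error probability, or a mean RT
per trial type — the measure is evaluated on each half of each participant,
the two half-score vectors are correlated across participants (Pearson), and
the correlation is corrected for halved test length by the Spearman–Brown
prophecy formula

    r_SB = 2 r / (1 + r).

Three split strategies are supported: the systematic first/second and
odd/even splits, and random balanced splits. Sampling-based estimation draws
``n_samples`` (default 1000) independent random splits — independently per
participant, since trial counts differ — evaluates all requested measures on
the *same* split of each iteration, and summarizes the resulting r_SB
distribution by its median and the 95% highest density interval (HDI), the
narrowest contiguous window of the sorted sample containing 95% of it.

Half scores use globally computed trial labels, error flags, and RT validity
masks: splitting never relabels trials. Error-count half-scores are raw
counts (halves are balanced by construction); conditional error
probabilities divide by the half's trial-type count. Participants with an
undefined score in either half (e.g. no valid inference trial) are dropped
pairwise for that measure and split, with the contributing pair count
reported. A negative r_SB is reported as computed, never truncated at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .filtering import FilterConfig, valid_rt_mask
from .scoring import (
    REPEAT,
    SWITCH,
    UNLABELED,
    ErrorFlags,
    TrialTypeLabels,
    classify_trial_types,
    error_flags,
)
from .task import ParticipantLog

__all__ = [
    "SplitSpec",
    "Measure",
    "DEFAULT_MEASURES",
    "ALL_MEASURES",
    "get_measure",
    "PreparedParticipant",
    "prepare_cohort",
    "ReliabilityEstimate",
    "SampledReliability",
    "split_first_second",
    "split_odd_even",
    "split_random",
    "half_scores",
    "spearman_brown",
    "estimate",
    "sample_reliability",
    "sample_reliability_multi",
    "hdi",
]


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitSpec:
    """Assignment of one participant's trials to half A (True) or B (False)."""

    in_a: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "in_a", np.asarray(self.in_a, dtype=bool))
        n_a = int(self.in_a.sum())
        if abs(2 * n_a - len(self.in_a)) > 1:
            raise ValueError("halves must be balanced to within one trial")

    def __len__(self) -> int:
        return len(self.in_a)


def _check_n(n: int) -> None:
    if n < 2:
        raise ValueError("a split needs at least 2 trials")


def split_first_second(n: int) -> SplitSpec:
    """First ``ceil(n/2)`` trials to half A, the rest to half B."""
    _check_n(n)
    k = -(-n // 2)
    in_a = np.zeros(n, dtype=bool)
    in_a[:k] = True
    return SplitSpec(in_a)


def split_odd_even(n: int) -> SplitSpec:
    """Odd trial numbers (1-based) to half A, even to half B."""
    _check_n(n)
    return SplitSpec(np.arange(n) % 2 == 0)


def split_random(n: int, rng: np.random.Generator) -> SplitSpec:
    """Uniformly random balanced split; for odd n the extra trial lands in
    either half with probability 1/2."""
    _check_n(n)
    k = n // 2
    if n % 2:
        k += int(rng.integers(2))
    in_a = np.zeros(n, dtype=bool)
    in_a[rng.permutation(n)[:k]] = True
    return SplitSpec(in_a)


# ---------------------------------------------------------------------------
# measures and prepared cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Measure:
    """A per-participant performance measure evaluable on any subset of trials.

    ``numerator``/``denominator`` name per-trial term vectors of a
    :class:`PreparedParticipant`; the score of a half is the numerator sum,
    divided by the denominator sum when a denominator is set (undefined when
    that sum is zero). This additive form is what makes a measure evaluable
    on an arbitrary half using only globally pre-computed flags.
    """

    name: str
    numerator: str
    denominator: str | None = None

    def score_half(self, prep: "PreparedParticipant", in_half: np.ndarray) -> float:
        """Evaluate the measure on the trials selected by ``in_half``."""
        num = float(prep.terms[self.numerator][in_half].sum())
        if self.denominator is None:
            return num
        den = float(prep.terms[self.denominator][in_half].sum())
        return num / den if den > 0 else float("nan")


#: the standard measure set: the three error counts and the
#: three per-type mean RTs ...
DEFAULT_MEASURES: tuple[Measure, ...] = (
    Measure("pe", "pe"),
    Measure("sle", "sle"),
    Measure("ie", "ie"),
    Measure("rt_switch", "rt_valid_switch", "valid_switch"),
    Measure("rt_repeat", "rt_valid_repeat", "valid_repeat"),
    Measure("rt_inference", "rt_valid_inference", "valid_inference"),
)

#: ... plus conditional error probabilities (errors per trial of the eligible type)
ALL_MEASURES: tuple[Measure, ...] = DEFAULT_MEASURES + (
    Measure("p_pe", "pe", "switch"),
    Measure("p_sle", "sle", "repeat"),
    Measure("p_ie", "ie", "inference"),
)

_MEASURES_BY_NAME = {m.name: m for m in ALL_MEASURES}


def get_measure(name: str) -> Measure:
    try:
        return _MEASURES_BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown measure {name!r}; available: {sorted(_MEASURES_BY_NAME)}"
        ) from None


@dataclass
class PreparedParticipant:
    """One participant with labels, error flags, RT mask, and term vectors."""

    log: ParticipantLog
    labels: TrialTypeLabels
    errors: ErrorFlags
    rt_mask: np.ndarray
    terms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.labels)


def prepare_participant(
    log: ParticipantLog, filter_config: FilterConfig | None = None
) -> PreparedParticipant:
    """Classify, score, and RT-screen one log; cache per-trial term vectors."""
    labels = classify_trial_types(log)
    errors = error_flags(log, labels)
    mask = valid_rt_mask(log, labels, errors, filter_config)
    rt = log.experimental.rt_ms
    f = np.float64
    terms = {
        "pe": errors.pe.astype(f),
        "sle": errors.sle.astype(f),
        "ie": errors.ie.astype(f),
        "switch": labels.is_switch.astype(f),
        "repeat": labels.is_repeat.astype(f),
        "inference": labels.is_inference.astype(f),
    }
    for t in ("switch", "repeat", "inference"):
        valid = terms[t] * mask
        terms[f"valid_{t}"] = valid
        terms[f"rt_valid_{t}"] = valid * rt
    return PreparedParticipant(log=log, labels=labels, errors=errors, rt_mask=mask, terms=terms)


def prepare_cohort(
    cohort: list[ParticipantLog], filter_config: FilterConfig | None = None
) -> list[PreparedParticipant]:
    """Prepare every log of a (screened) cohort for reliability analysis."""
    return [prepare_participant(log, filter_config) for log in cohort]


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReliabilityEstimate:
    """Split-half reliability of one measure under one split strategy."""

    measure: str
    strategy: str  # "first_second" | "odd_even" | "random"
    r: float  # Pearson correlation between half scores (nan if undefined)
    r_sb: float  # Spearman–Brown-corrected coefficient
    n_pairs: int  # participants contributing defined score pairs

    @property
    def defined(self) -> bool:
        return math.isfinite(self.r)


@dataclass(frozen=True)
class SampledReliability:
    """Distribution of r_SB over random splits, with median and 95% HDI."""

    measure: str
    n_samples: int
    r_sb: np.ndarray  # length n_samples; nan marks undefined iterations
    median: float
    hdi_low: float
    hdi_high: float
    hdi_mass: float
    n_undefined: int
    min_n_pairs: int

    @property
    def strategy(self) -> str:
        return "random"


def spearman_brown(r: float) -> float:
    """Project a half-test correlation to full length: ``2r / (1 + r)``.

    Strictly increasing on (-1, 1]; undefined at r = -1 (returned as nan).
    """
    if math.isnan(r):
        return float("nan")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"a correlation must lie in [-1, 1], got {r}")
    if r == -1.0:
        return float("nan")
    return 2.0 * r / (1.0 + r)


def half_scores(
    prepared: list[PreparedParticipant],
    splits: list[SplitSpec],
    measure: Measure,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate a measure on both halves of every participant.

    Returns ``(a, b)`` score vectors; an undefined half-score is nan.
    """
    if len(splits) != len(prepared):
        raise ValueError("one split per prepared participant is required")
    a = np.empty(len(prepared))
    b = np.empty(len(prepared))
    for i, (prep, split) in enumerate(zip(prepared, splits)):
        if len(split) != prep.n_trials:
            raise ValueError(
                f"split length {len(split)} != trial count {prep.n_trials} "
                f"for participant {prep.log.participant_id}"
            )
        a[i] = measure.score_half(prep, split.in_a)
        b[i] = measure.score_half(prep, ~split.in_a)
    return a, b


def _pearson_pairwise(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Pearson r with pairwise deletion of undefined scores.

    Returns ``(r, n_pairs)``; r is nan when fewer than 3 pairs remain or a
    half-score vector is constant.
    """
    valid = np.isfinite(a) & np.isfinite(b)
    n = int(valid.sum())
    if n < 3:
        raise ValueError(f"only {n} participants with defined score pairs (< 3)")
    av, bv = a[valid], b[valid]
    sa, sb = av.std(), bv.std()
    if sa == 0.0 or sb == 0.0:
        return float("nan"), n
    r = float(np.corrcoef(av, bv)[0, 1])
    return min(max(r, -1.0), 1.0), n


_SYSTEMATIC = {"first_second": split_first_second, "odd_even": split_odd_even}


def estimate(
    prepared: list[PreparedParticipant],
    measure: Measure | str,
    strategy: str,
) -> ReliabilityEstimate:
    """Split-half reliability under a systematic split strategy."""
    if isinstance(measure, str):
        measure = get_measure(measure)
    try:
        splitter = _SYSTEMATIC[strategy]
    except KeyError:
        raise ValueError(
            f"strategy must be one of {sorted(_SYSTEMATIC)}, got {strategy!r}"
        ) from None
    splits = [splitter(p.n_trials) for p in prepared]
    a, b = half_scores(prepared, splits, measure)
    r, n_pairs = _pearson_pairwise(a, b)
    return ReliabilityEstimate(
        measure=measure.name, strategy=strategy, r=r, r_sb=spearman_brown(r), n_pairs=n_pairs
    )


def hdi(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval of a sample containing ``mass`` of it.

    The window spans ``ceil(mass * n)`` sorted values; ties go to the
    leftmost window. Requires at least 20 samples.
    """
    x = np.sort(np.asarray(samples, dtype=np.float64))
    if not 0.0 < mass <= 1.0:
        raise ValueError("mass must be in (0, 1]")
    n = len(x)
    if n < 20:
        raise ValueError(f"hdi needs at least 20 samples, got {n}")
    if np.any(~np.isfinite(x)):
        raise ValueError("hdi requires finite samples")
    m = math.ceil(mass * n)
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the leftmost tie
    return float(x[i]), float(x[i + m - 1])


# ---------------------------------------------------------------------------
# sampling-based estimation
# ---------------------------------------------------------------------------


def _random_half_matrix(
    n_trials: int, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_samples, n_trials) boolean matrix; each row a random balanced split."""
    u = rng.random((n_samples, n_trials))
    ranks = u.argsort(axis=1).argsort(axis=1)
    k = n_trials // 2
    if n_trials % 2:
        sizes = k + rng.integers(2, size=n_samples)[:, None]
    else:
        sizes = np.full((n_samples, 1), k)
    return ranks < sizes


def _stratified_half_matrix(
    prep: "PreparedParticipant", n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Random splits balanced within each trial-type stratum.

    Strata are unlabeled, non-inference switch, inference, and repeat
    trials; each stratum is split to within one trial, so the overall split
    can deviate from perfect balance by up to one trial per stratum.
    """
    n = prep.n_trials
    half = np.zeros((n_samples, n), dtype=bool)
    base, inf = prep.labels.base, prep.labels.is_inference
    strata = (
        np.flatnonzero(base == UNLABELED),
        np.flatnonzero((base == SWITCH) & ~inf),
        np.flatnonzero(inf),
        np.flatnonzero(base == REPEAT),
    )
    for idx in strata:
        if len(idx) == 0:
            continue
        if len(idx) == 1:
            half[:, idx[0]] = rng.integers(2, size=n_samples).astype(bool)
        else:
            half[:, idx] = _random_half_matrix(len(idx), n_samples, rng)
    return half


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-by-row Pearson r with pairwise deletion of nan columns.

    ``a`` and ``b`` are (n_samples, n_participants). Returns ``(r, n_pairs)``
    per row; rows with fewer than 3 pairs or zero variance get nan.
    """
    valid = np.isfinite(a) & np.isfinite(b)
    n = valid.sum(axis=1)
    a0 = np.where(valid, a, 0.0)
    b0 = np.where(valid, b, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sa, sb = a0.sum(1), b0.sum(1)
        saa, sbb, sab = (a0 * a0).sum(1), (b0 * b0).sum(1), (a0 * b0).sum(1)
        cov = sab - sa * sb / n
        va = saa - sa * sa / n
        vb = sbb - sb * sb / n
        r = cov / np.sqrt(va * vb)
    r[(n < 3) | (va <= 0) | (vb <= 0)] = np.nan
    return np.clip(r, -1.0, 1.0), n


def sample_reliability_multi(
    prepared: list[PreparedParticipant],
    measures: tuple[Measure, ...] | list[Measure] = DEFAULT_MEASURES,
    n_samples: int = 1000,
    rng: np.random.Generator | None = None,
    hdi_mass: float = 0.95,
    stratified: bool = False,
) -> dict[str, SampledReliability]:
    """Sampling-based split-half reliability for several measures at once.

    Each iteration draws one fresh random split per participant and evaluates
    every measure on that same split, mirroring how a single resampling run
    scores all performance indices together. Iterations where r is undefined
    for a measure (too few defined pairs, or a constant half-score vector)
    are excluded from that measure's summary and counted. ``stratified``
    balances each split within trial-type strata instead of over all trials
    (off by default: the reference procedure splits the total of a
    participant's completed trials).
    """
    if rng is None:
        raise ValueError("sampling requires a seeded numpy Generator")
    if not prepared:
        raise ValueError("empty cohort")
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    measures = [get_measure(m) if isinstance(m, str) else m for m in measures]

    # per-trial term matrix per participant -> one matmul per participant
    term_names: list[str] = []
    for m in measures:
        term_names.append(m.numerator)
        if m.denominator is not None:
            term_names.append(m.denominator)
    term_names = sorted(set(term_names))
    col = {t: j for j, t in enumerate(term_names)}

    n_p = len(prepared)
    sums_a = np.empty((n_samples, n_p, len(term_names)))
    totals = np.empty((n_p, len(term_names)))
    for i, prep in enumerate(prepared):
        if prep.n_trials < 2:
            raise ValueError(
                f"participant {prep.log.participant_id} has < 2 experimental trials"
            )
        tm = np.column_stack([prep.terms[t] for t in term_names])
        if stratified:
            half = _stratified_half_matrix(prep, n_samples, rng)
        else:
            half = _random_half_matrix(prep.n_trials, n_samples, rng)
        sums_a[:, i, :] = half.astype(np.float64) @ tm
        totals[i] = tm.sum(axis=0)
    sums_b = totals[None, :, :] - sums_a

    out: dict[str, SampledReliability] = {}
    for m in measures:
        a = sums_a[:, :, col[m.numerator]]
        b = sums_b[:, :, col[m.numerator]]
        if m.denominator is not None:
            with np.errstate(invalid="ignore", divide="ignore"):
                a = np.where(sums_a[:, :, col[m.denominator]] > 0,
                             a / sums_a[:, :, col[m.denominator]], np.nan)
                b = np.where(sums_b[:, :, col[m.denominator]] > 0,
                             b / sums_b[:, :, col[m.denominator]], np.nan)
        r, n_pairs = _rowwise_pearson(a, b)
        with np.errstate(invalid="ignore", divide="ignore"):
            r_sb = np.where(r > -1.0, 2.0 * r / (1.0 + r), np.nan)
        finite = np.isfinite(r_sb)
        if not finite.any():
            raise ValueError(f"r undefined on every sampled split for measure {m.name}")
        low, high = hdi(r_sb[finite], hdi_mass)
        out[m.name] = SampledReliability(
            measure=m.name,
            n_samples=n_samples,
            r_sb=r_sb,
            median=float(np.median(r_sb[finite])),
            hdi_low=low,
            hdi_high=high,
            hdi_mass=hdi_mass,
            n_undefined=int((~finite).sum()),
            min_n_pairs=int(n_pairs.min()),
        )
    return out


def sample_reliability(
    prepared: list[PreparedParticipant],
    measure: Measure | str,
    n_samples: int = 1000,
    rng: np.random.Generator | None = None,
    hdi_mass: float = 0.95,
    stratified: bool = False,
) -> SampledReliability:
    """Sampling-based split-half reliability of a single measure."""
    if isinstance(measure, str):
        measure = get_measure(measure)
    return sample_reliability_multi(
        prepared, (measure,), n_samples, rng, hdi_mass, stratified
    )[measure.name]
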