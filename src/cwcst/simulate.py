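"""Generative model of cWCST participants and cohorts.

Real participants differ stably from one another in how often they
perseverate, lose the cognitive set, or fail category inference, and in how
fast they respond — it is exactly this between-participant heterogeneity
that split-half reliability quantifies. This module models a participant as
a memoryless stochastic policy (:class:`AgentParams`): on each trial the
agent commits each error type with a fixed probability given the trial
context, and RTs are log-normal per trial context with an optional linear
within-session drift in both error log-odds and log-RT (learning or
fatigue). A cohort (:class:`PopulationConfig`) draws agent parameters
independently per participant — beta distributions for probabilities,
normal distributions (with a shared person-level speed factor) for log-RT
locations, normal distributions for drift slopes.

The default population is calibrated so that a simulated cohort reproduces
the descriptive moments reported for a real young-adult cohort of N = 375:
about 168 completed trials, 12.2 perseveration errors (SD 13.7), 5.0
set-loss errors (SD 7.1), 8.5 inference errors (SD 8.8) per participant,
and mean RTs near 1241/1835/1700 ms on repeat/switch/inference trials (SDs
441/694/636 ms).

:func:`oracle_reliability` provides a brute-force Monte-Carlo reference for
parameter-recovery tests: it simulates many independent cohorts, applies one
random split to each, and recomputes the split-half coefficient directly
from the trial-type and error definitions, sharing no scoring or resampling
code with the analysis modules (only the Spearman–Brown formula itself).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .filtering import FilterConfig, screen_participants
from .reliability import spearman_brown
from .task import COLOR, NUMBER, OTHER, SHAPE, ParticipantLog, StimulusCard, TaskConfig, run_session

__all__ = [
    "AgentParams",
    "BetaSpec",
    "PopulationConfig",
    "TrialContext",
    "OracleReliability",
    "sample_population",
    "agent_response",
    "generate_cohort",
    "oracle_reliability",
]

# RT contexts: index into rt_location / rt_scale
CTX_REPEAT, CTX_SWITCH, CTX_INFERENCE = 0, 1, 2

#: descriptive moments (mean, SD) of the reference young-adult cohort that the
#: default :class:`PopulationConfig` is calibrated to reproduce after the
#: validity screen: error counts per participant and per-type mean RT in ms
CALIBRATION_TARGETS: dict[str, tuple[float, float]] = {
    "pe": (12.16, 13.65),
    "sle": (5.03, 7.07),
    "ie": (8.46, 8.82),
    "rt_switch": (1835.0, 694.0),
    "rt_repeat": (1241.0, 441.0),
    "rt_inference": (1700.0, 636.0),
}


@dataclass(frozen=True)
class AgentParams:
    """Behavioral policy of one simulated participant.

    Error probabilities are per eligible trial: ``p_persev`` on switch
    trials, ``p_setloss`` on repeat trials, ``p_inferr`` on inference trials
    (given the agent did not perseverate). When erring by switching away or
    failing inference, the no-match key is pressed with probability
    ``p_other``. RTs are log-normal with context-specific location and scale
    (log-ms; contexts: repeat/first, switch, inference). ``drift_error``
    shifts all error log-odds by that amount per trial; ``drift_rt`` shifts
    the log-RT location per trial.
    """

    participant_id: str = "sim"
    p_persev: float = 0.0
    p_setloss: float = 0.0
    p_inferr: float = 0.0
    p_other: float = 0.0
    rt_location: tuple[float, float, float] = (7.0, 7.4, 7.3)
    rt_scale: tuple[float, float, float] = (0.45, 0.5, 0.65)
    drift_error: float = 0.0
    drift_rt: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_persev", "p_setloss", "p_inferr", "p_other"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if any(s <= 0 for s in self.rt_scale):
            raise ValueError("rt_scale entries must be positive")

    @classmethod
    def error_free(cls, participant_id: str = "ideal") -> "AgentParams":
        """An agent that never errs (it may still guess wrong right after a
        covert switch, which is not an error)."""
        return cls(participant_id=participant_id)


@dataclass(frozen=True)
class BetaSpec:
    """Between-participant distribution of a probability, as mean and SD.

    ``sd = 0`` is a point mass. Otherwise the pair is converted to a Beta
    distribution by moment matching, which requires
    ``sd**2 < mean * (1 - mean)``.
    """

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean <= 1.0:
            raise ValueError(f"mean must be a probability, got {self.mean}")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.sd > 0:
            limit = self.mean * (1.0 - self.mean)
            if self.sd**2 >= limit:
                raise ValueError(
                    f"sd {self.sd} too large for a Beta with mean {self.mean} "
                    f"(needs sd^2 < {limit:.4g})"
                )

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0.0:
            return np.full(size, self.mean)
        kappa = self.mean * (1.0 - self.mean) / self.sd**2 - 1.0
        return rng.beta(self.mean * kappa, (1.0 - self.mean) * kappa, size=size)


@dataclass(frozen=True)
class PopulationConfig:
    """Cohort-level hyperparameters for sampling agents.

    ``rt_log_mu`` are population log-RT locations per context
    (repeat/switch/inference, log-ms); a shared standard-normal person
    factor scaled by ``rt_log_between_sd`` shifts all three jointly (slow
    participants are slow everywhere), and ``rt_log_within_sd`` is the
    trial-to-trial log-scale. Drift slopes are normal with mean zero.
    """

    n_participants: int = 375
    persev: BetaSpec = BetaSpec(0.140, 0.121)
    setloss: BetaSpec = BetaSpec(0.0575, 0.080)
    inferr: BetaSpec = BetaSpec(0.172, 0.168)
    other: BetaSpec = BetaSpec(0.05, 0.0)
    rt_log_mu: tuple[float, float, float] = (6.974, 7.4137, 7.3024)
    rt_log_between_sd: tuple[float, float, float] = (0.345, 0.365, 0.33)
    rt_log_within_sd: tuple[float, float, float] = (0.45, 0.50, 0.65)
    drift_error_sd: float = 0.0
    drift_rt_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("a cohort needs at least 2 participants")
        if any(s < 0 for s in self.rt_log_between_sd) or any(
            s <= 0 for s in self.rt_log_within_sd
        ):
            raise ValueError("RT spread parameters must admit positive scales")
        if self.drift_error_sd < 0 or self.drift_rt_sd < 0:
            raise ValueError("drift SDs must be non-negative")


def sample_population(
    config: PopulationConfig, rng: np.random.Generator
) -> list[AgentParams]:
    """Draw ``n_participants`` independent agents from the population."""
    n = config.n_participants
    pp = config.persev.sample(n, rng)
    ps = config.setloss.sample(n, rng)
    pi = config.inferr.sample(n, rng)
    po = config.other.sample(n, rng)
    z = rng.standard_normal(n)  # shared person-level speed factor
    locs = np.asarray(config.rt_log_mu)[None, :] + z[:, None] * np.asarray(
        config.rt_log_between_sd
    )
    de = (
        rng.normal(0.0, config.drift_error_sd, size=n)
        if config.drift_error_sd > 0
        else np.zeros(n)
    )
    dr = (
        rng.normal(0.0, config.drift_rt_sd, size=n)
        if config.drift_rt_sd > 0
        else np.zeros(n)
    )
    width = len(str(n))
    return [
        AgentParams(
            participant_id=f"sim{i + 1:0{width}d}",
            p_persev=float(pp[i]),
            p_setloss=float(ps[i]),
            p_inferr=float(pi[i]),
            p_other=float(po[i]),
            rt_location=(float(locs[i, 0]), float(locs[i, 1]), float(locs[i, 2])),
            rt_scale=config.rt_log_within_sd,
            drift_error=float(de[i]),
            drift_rt=float(dr[i]),
        )
        for i in range(n)
    ]


@dataclass(frozen=True)
class TrialContext:
    """What the agent knows when responding: the stimulus, the previous
    feedback and applied category, whether the trial is an inference trial,
    the (hidden) prevailing category, and the 1-based trial index."""

    stimulus: StimulusCard
    prevailing: int
    trial_index: int = 1
    prev_feedback: bool | None = None  # None on the first trial of a block
    prev_applied: int | None = None
    is_inference: bool = False


def _drifted(p: float, shift: float) -> float:
    if shift == 0.0 or p <= 0.0 or p >= 1.0:
        return p
    return 1.0 / (1.0 + math.exp(-(math.log(p / (1.0 - p)) + shift)))


def agent_response(
    agent: AgentParams, state: TrialContext, rng: np.random.Generator
) -> tuple[int, float]:
    """One step of the behavioral policy: a key press and an RT.

    Reference single-trial implementation of the policy that
    :func:`cwcst.task.run_session` runs in fused form: repeat the previous
    category with ``p_persev`` after negative feedback, abandon it with
    ``p_setloss`` after positive feedback, and — on inference trials, when
    not perseverating — apply the deducible prevailing category with
    probability ``1 - p_inferr``.
    """
    stim = state.stimulus
    shift = agent.drift_error * (state.trial_index - 1)
    prev = state.prev_applied

    if state.prev_feedback is None:
        applied = int(rng.integers(3))
        ctx = CTX_REPEAT
    elif state.prev_feedback:
        ctx = CTX_REPEAT
        if rng.random() < _drifted(agent.p_setloss, shift):
            if rng.random() < agent.p_other:
                applied = OTHER
            else:
                applied = (prev + 1 + int(rng.integers(2))) % 3
        else:
            applied = prev
    else:
        ctx = CTX_INFERENCE if state.is_inference else CTX_SWITCH
        if rng.random() < _drifted(agent.p_persev, shift):
            applied = prev
        elif state.is_inference:
            if rng.random() < 1.0 - _drifted(agent.p_inferr, shift):
                applied = state.prevailing
            elif rng.random() < agent.p_other:
                applied = OTHER
            elif prev is not None and prev <= 2:
                applied = 3 - prev - state.prevailing
            else:
                applied = (state.prevailing + 1 + int(rng.integers(2))) % 3
        elif prev is not None and prev <= 2:
            applied = (prev + 1 + int(rng.integers(2))) % 3
        else:
            applied = int(rng.integers(3))

    if applied == OTHER:
        response = 10 - stim.number - stim.color - stim.shape
    elif applied == NUMBER:
        response = stim.number
    elif applied == COLOR:
        response = stim.color
    else:
        response = stim.shape
    rt = math.exp(
        agent.rt_location[ctx]
        + agent.drift_rt * (state.trial_index - 1)
        + agent.rt_scale[ctx] * rng.standard_normal()
    )
    return response, rt


def generate_cohort(
    config: PopulationConfig,
    task_config: TaskConfig | None = None,
    rng: np.random.Generator | None = None,
    return_params: bool = False,
):
    """Simulate a full cohort of sessions.

    Returns the list of trial logs, or ``(logs, agents)`` when
    ``return_params`` is set (for parameter-recovery work).
    """
    if rng is None:
        raise ValueError("generate_cohort requires a seeded numpy Generator")
    if task_config is None:
        task_config = TaskConfig()
    agents = sample_population(config, rng)
    logs = [run_session(agent, task_config, rng) for agent in agents]
    return (logs, agents) if return_params else logs


# ---------------------------------------------------------------------------
# brute-force scoring (independent of the scoring/filtering/reliability code)
# ---------------------------------------------------------------------------


def _brute_half_scores(log: ParticipantLog, in_a, measure: str) -> tuple[float, float]:
    """Score one measure on both halves straight from the definitions.

    Deliberately re-derives trial types, errors, and the RT mask with plain
    loops so that the Monte-Carlo oracle shares nothing with the analysis
    modules beyond the Spearman-Brown formula.
    """
    exp = log.experimental
    fb = exp.feedback.tolist()
    ap = exp.applied.tolist()
    pv = exp.prevailing.tolist()
    rt = exp.rt_ms.tolist()
    n = len(fb)
    in_a = list(in_a)

    switch = [False] * n
    repeat = [False] * n
    infer = [False] * n
    for t in range(1, n):
        if fb[t - 1]:
            repeat[t] = True
        else:
            switch[t] = True
        if t >= 2 and switch[t - 1] and ap[t - 1] != ap[t - 2] and not fb[t - 1]:
            infer[t] = True

    pe = [False] * n
    sle = [False] * n
    ie = [False] * n
    for t in range(1, n):
        if switch[t] and ap[t] == ap[t - 1] and ap[t] != 3:
            pe[t] = True
        if repeat[t] and ap[t] != ap[t - 1]:
            sle[t] = True
    for t in range(n):
        if infer[t] and ap[t] != pv[t]:
            ie[t] = True

    if measure in ("pe", "sle", "ie"):
        flags = {"pe": pe, "sle": sle, "ie": ie}[measure]
        a = sum(1.0 for t in range(n) if flags[t] and in_a[t])
        b = sum(1.0 for t in range(n) if flags[t] and not in_a[t])
        return a, b

    if measure.startswith("rt_"):
        kind = {"rt_switch": switch, "rt_repeat": repeat, "rt_inference": infer}[measure]
        m = sum(rt) / n
        sd = math.sqrt(sum((x - m) ** 2 for x in rt) / (n - 1))
        cutoff = m + 3.0 * sd
        valid = [
            kind[t] and rt[t] >= 100.0 and rt[t] <= cutoff and not (pe[t] or sle[t] or ie[t])
            for t in range(n)
        ]
        out = []
        for half in (True, False):
            xs = [rt[t] for t in range(n) if valid[t] and in_a[t] == half]
            out.append(sum(xs) / len(xs) if xs else float("nan"))
        return out[0], out[1]

    raise ValueError(f"oracle does not know measure {measure!r}")


@dataclass(frozen=True)
class OracleReliability:
    """Monte-Carlo reference distribution of single-split r_SB values."""

    measure: str
    n_mc: int
    r_sb: np.ndarray  # one value per simulated cohort (nan = undefined)
    mean: float
    sd: float  # cohort-to-cohort spread
    se: float  # Monte-Carlo standard error of the mean
    n_undefined: int


def oracle_reliability(
    config: PopulationConfig,
    task_config: TaskConfig | None = None,
    measure: str = "pe",
    n_mc: int = 200,
    rng: np.random.Generator | None = None,
    screen: bool = True,
) -> OracleReliability:
    """Brute-force expected split-half reliability of a measure.

    Simulates ``n_mc`` independent cohorts; for each, applies the cohort
    validity screen (optional), draws ONE uniformly random balanced split
    per participant, scores both halves straight from the definitions, and
    computes the Spearman-Brown-corrected Pearson correlation. Reports the
    mean, the cohort-to-cohort SD, and the Monte-Carlo standard error.
    """
    if rng is None:
        raise ValueError("oracle_reliability requires a seeded numpy Generator")
    if n_mc < 100:
        raise ValueError("n_mc must be at least 100 for a stable oracle")
    if task_config is None:
        task_config = TaskConfig()

    r_sb = np.full(n_mc, np.nan)
    for k in range(n_mc):
        logs = generate_cohort(config, task_config, rng)
        if screen:
            res = screen_participants(logs, FilterConfig())
            logs = [log for log, ok in zip(logs, res.included) if ok]
        a_scores, b_scores = [], []
        for log in logs:
            n = log.n_experimental
            half = n // 2 + (int(rng.integers(2)) if n % 2 else 0)
            in_a = np.zeros(n, dtype=bool)
            in_a[rng.permutation(n)[:half]] = True
            a, b = _brute_half_scores(log, in_a, measure)
            a_scores.append(a)
            b_scores.append(b)
        a_arr = np.asarray(a_scores)
        b_arr = np.asarray(b_scores)
        ok = np.isfinite(a_arr) & np.isfinite(b_arr)
        if ok.sum() >= 3 and a_arr[ok].std() > 0 and b_arr[ok].std() > 0:
            r = float(np.corrcoef(a_arr[ok], b_arr[ok])[0, 1])
            if r > -1.0:
                r_sb[k] = spearman_brown(r)
    finite = np.isfinite(r_sb)
    n_def = int(finite.sum())
    if n_def == 0:
        mean = sd = se = float("nan")
    else:
        vals = r_sb[finite]
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if n_def > 1 else float("nan")
        se = sd / math.sqrt(n_def) if n_def > 1 else float("nan")
    return OracleReliability(
        measure=measure,
        n_mc=n_mc,
        r_sb=r_sb,
        mean=mean,
        sd=sd,
        se=se,
        n_undefined=int((~finite).sum()),
    )
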