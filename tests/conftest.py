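"""Shared fixtures: hand-built trial logs and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from cwcst import AgentParams, ParticipantLog, PopulationConfig, TaskConfig, generate_cohort
from cwcst.task import CATEGORY_CODES, StimulusCard, TrialRecord, run_session

#: the canonical worked-example card: one green cross (matches key 1 on number,
#: key 2 on color, key 3 on shape; key 4 matches nothing)
GREEN_CROSS = StimulusCard(number=1, color=2, shape=3)

_RESPONSE_FOR = {"number": 1, "color": 2, "shape": 3, "other": 4}


def make_log(
    pid: str,
    seq: list[tuple[str, str]],
    rts: list[float] | None = None,
    block: str = "experimental",
) -> ParticipantLog:
    """Build a log from (applied_category, prevailing_category) name pairs.

    Every trial shows the green-cross card, so the response follows from the
    applied category; feedback follows from applied vs prevailing.
    """
    if rts is None:
        rts = [1000.0] * len(seq)
    records = []
    for i, ((applied, prevailing), rt) in enumerate(zip(seq, rts), start=1):
        records.append(
            TrialRecord(
                participant_id=pid,
                trial_index=i,
                block=block,
                stimulus=GREEN_CROSS,
                prevailing_category=CATEGORY_CODES[prevailing],
                response=_RESPONSE_FOR[applied],
                applied_category=CATEGORY_CODES[applied],
                feedback=applied == prevailing,
                rt_ms=rt,
            )
        )
    return ParticipantLog.from_records(records)


@pytest.fixture(scope="session")
def switch_pe_log() -> ParticipantLog:
    """Shape sorted under a color rule, then repeated: a switch trial with a
    perseveration error on the continuation."""
    return make_log("ex_pe", [("shape", "color"), ("shape", "color")])


@pytest.fixture(scope="session")
def repeat_sle_log() -> ParticipantLog:
    """Shape correctly sorted, then abandoned for color: a repeat trial with
    a set-loss error on the continuation."""
    return make_log("ex_sle", [("shape", "shape"), ("color", "shape")])


@pytest.fixture(scope="session")
def inference_ie_log() -> ParticipantLog:
    """Shape then number both disconfirmed: the third trial is an inference
    trial (color is deducible) and the shape response is an inference error."""
    return make_log(
        "ex_ie", [("shape", "color"), ("number", "color"), ("shape", "color")]
    )


def random_agent(rng: np.random.Generator, pid: str = "rand", **over) -> AgentParams:
    """An agent with broadly random error probabilities, for property tests."""
    params = dict(
        participant_id=pid,
        p_persev=float(rng.uniform(0, 0.6)),
        p_setloss=float(rng.uniform(0, 0.3)),
        p_inferr=float(rng.uniform(0, 0.6)),
        p_other=float(rng.uniform(0, 0.3)),
        rt_location=(7.0, 7.4, 7.3),
        rt_scale=(0.45, 0.5, 0.65),
    )
    params.update(over)
    return AgentParams(**params)


def random_logs(n: int, seed: int) -> list[ParticipantLog]:
    """Simulated logs from agents with broadly random parameters."""
    rng = np.random.default_rng(seed)
    return [
        run_session(random_agent(rng, pid=f"r{i}"), TaskConfig(), rng) for i in range(n)
    ]


@pytest.fixture(scope="session")
def small_cohort() -> list[ParticipantLog]:
    """A 60-participant cohort from the default population (fixed seed)."""
    return generate_cohort(
        PopulationConfig(n_participants=60), rng=np.random.default_rng(42)
    )
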