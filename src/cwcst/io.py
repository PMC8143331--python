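"""Reading and writing trial logs, score tables, and configuration files.

Trial logs travel as one CSV row per trial:

    participant_id, block, trial_index, stim_number, stim_color, stim_shape,
    prevailing_category, response, applied_category, feedback, rt_ms

with human-readable values (``block`` practice/experimental, colors and
shapes by name, categories color/shape/number/other, feedback
positive/negative). The reader validates every row: stimulus cards must be
unambiguous, and ``applied_category`` and ``feedback`` are recomputed from
the stimulus, response, and prevailing category — a file that disagrees with
its own recomputation is rejected with the offending row named.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .task import (
    CATEGORY_CODES,
    CATEGORY_NAMES,
    COLOR_CODES,
    COLOR_NAMES,
    OTHER,
    SHAPE_CODES,
    SHAPE_NAMES,
    ParticipantLog,
)

__all__ = [
    "TRIAL_LOG_COLUMNS",
    "logs_to_frame",
    "frame_to_logs",
    "write_trial_logs",
    "read_trial_logs",
    "load_config_file",
]

TRIAL_LOG_COLUMNS = (
    "participant_id",
    "block",
    "trial_index",
    "stim_number",
    "stim_color",
    "stim_shape",
    "prevailing_category",
    "response",
    "applied_category",
    "feedback",
    "rt_ms",
)


def logs_to_frame(logs: Iterable[ParticipantLog]) -> pd.DataFrame:
    """Flatten trial logs into the canonical one-row-per-trial DataFrame."""
    parts = []
    for log in logs:
        parts.append(
            pd.DataFrame(
                {
                    "participant_id": log.participant_id,
                    "block": pd.Series(log.is_practice).map(
                        {True: "practice", False: "experimental"}
                    ),
                    "trial_index": log.trial_index,
                    "stim_number": log.stim_number,
                    "stim_color": pd.Series(log.stim_color).map(COLOR_NAMES),
                    "stim_shape": pd.Series(log.stim_shape).map(SHAPE_NAMES),
                    "prevailing_category": pd.Series(log.prevailing).map(CATEGORY_NAMES),
                    "response": log.response,
                    "applied_category": pd.Series(log.applied).map(CATEGORY_NAMES),
                    "feedback": pd.Series(log.feedback).map(
                        {True: "positive", False: "negative"}
                    ),
                    "rt_ms": log.rt_ms,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def _bad_row(df: pd.DataFrame, mask, message: str) -> None:
    import numpy as np

    idx = np.flatnonzero(np.asarray(mask))
    if len(idx):
        # +2: 1-based and a header line
        raise ValueError(f"invalid trial log, row {int(idx[0]) + 2}: {message}")


def frame_to_logs(df: pd.DataFrame, validate: bool = True) -> list[ParticipantLog]:
    """Parse the canonical trial-log DataFrame into per-participant logs.

    ``applied_category`` and ``feedback`` are recomputed from the stimulus,
    response, and prevailing category; inconsistent rows are rejected.
    """
    import numpy as np

    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log is missing columns: {missing}")
    df = df.reset_index(drop=True)

    block = df["block"].astype(str)
    _bad_row(df, ~block.isin(["practice", "experimental"]), "unknown block")
    stim_n = pd.to_numeric(df["stim_number"], errors="coerce")
    _bad_row(df, ~stim_n.isin([1, 2, 3, 4]), "stim_number must be 1-4")
    color = df["stim_color"].astype(str).map(COLOR_CODES)
    _bad_row(df, color.isna(), f"stim_color must be one of {sorted(COLOR_CODES)}")
    shape = df["stim_shape"].astype(str).map(SHAPE_CODES)
    _bad_row(df, shape.isna(), f"stim_shape must be one of {sorted(SHAPE_CODES)}")
    prevailing = df["prevailing_category"].astype(str).map(CATEGORY_CODES)
    _bad_row(
        df,
        prevailing.isna() | (prevailing == OTHER),
        "prevailing_category must be color/shape/number",
    )
    response = pd.to_numeric(df["response"], errors="coerce")
    _bad_row(df, ~response.isin([1, 2, 3, 4]), "response must be a key position 1-4")
    applied = df["applied_category"].astype(str).map(CATEGORY_CODES)
    _bad_row(df, applied.isna(), "unknown applied_category")
    feedback = df["feedback"].astype(str)
    _bad_row(df, ~feedback.isin(["positive", "negative"]), "unknown feedback")
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    _bad_row(df, rt.isna() | (rt <= 0), "rt_ms must be a positive number")

    n = stim_n.to_numpy(dtype=np.int64)
    c = color.to_numpy(dtype=np.int64)
    s = shape.to_numpy(dtype=np.int64)
    pv = prevailing.to_numpy(dtype=np.int64)
    resp = response.to_numpy(dtype=np.int64)

    _bad_row(df, (n == c) | (n == s) | (c == s), "ambiguous stimulus card")
    recomputed = np.full(len(df), OTHER, dtype=np.int64)
    recomputed[resp == c] = CATEGORY_CODES["color"]
    recomputed[resp == s] = CATEGORY_CODES["shape"]
    recomputed[resp == n] = CATEGORY_CODES["number"]
    _bad_row(
        df,
        recomputed != applied.to_numpy(dtype=np.int64),
        "applied_category disagrees with stimulus/response",
    )
    fb = (feedback == "positive").to_numpy()
    _bad_row(df, fb != (recomputed == pv), "feedback disagrees with applied vs prevailing")

    logs = []
    for pid, grp in df.groupby("participant_id", sort=False):
        i = grp.index.to_numpy()
        log = ParticipantLog(
            str(pid),
            is_practice=(block.to_numpy() == "practice")[i],
            trial_index=pd.to_numeric(df["trial_index"]).to_numpy(dtype=np.int64)[i],
            stim_number=n[i],
            stim_color=c[i],
            stim_shape=s[i],
            prevailing=pv[i],
            response=resp[i],
            applied=recomputed[i],
            feedback=fb[i],
            rt_ms=rt.to_numpy(dtype=np.float64)[i],
        )
        if validate:
            try:
                log.validate()
            except ValueError as err:
                raise ValueError(f"participant {pid}: {err}") from None
        logs.append(log)
    return logs


def write_trial_logs(logs: Iterable[ParticipantLog], path: str | Path) -> None:
    logs_to_frame(logs).to_csv(path, index=False)


def read_trial_logs(path: str | Path) -> list[ParticipantLog]:
    return frame_to_logs(pd.read_csv(path))


def load_config_file(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data
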