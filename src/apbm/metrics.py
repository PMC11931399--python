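"""Per-session performance index and difficulty features.

The performance index of a session is the correct-response rate divided by
the median of the log-transformed response times,

    p_t = accuracy / median(log RT),

with RTs in milliseconds, natural logarithm, and a 10 ms floor so that the
denominator is strictly positive.  The difficulty features of a session are
the intended training ratio (ITR), its square, and the sample standard
deviation of the ITRs over a rolling window of the most recent ``k``
sessions (``k = 3`` by default), which captures how unpredictably the
difficulty has been moving.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .session_engine import SessionRecord, TrialResult

__all__ = [
    "RT_FLOOR_MS",
    "DEFAULT_SD_WINDOW",
    "PerformanceIndex",
    "DifficultyFeatures",
    "InsufficientHistoryError",
    "performance_index",
    "rolling_itr_sd",
    "difficulty_features",
    "session_metrics",
]

RT_FLOOR_MS = 10.0
DEFAULT_SD_WINDOW = 3


class InsufficientHistoryError(ValueError):
    """Raised when a rolling statistic is requested on too short a history."""


@dataclass(frozen=True)
class PerformanceIndex:
    """Session performance: accuracy over the median log response time."""

    value: float
    accuracy: float
    median_log_rt: float


@dataclass(frozen=True)
class DifficultyFeatures:
    """Difficulty features of the latest session in an ITR history.

    ``itr_sd_k`` is ``None`` when fewer than ``k`` sessions exist, which is
    distinguishable from a genuine zero (a constant recent history).
    """

    itr: float
    itr_sq: float
    itr_sd_k: float | None
    k: int


def performance_index(record: SessionRecord | Sequence[TrialResult]) -> PerformanceIndex:
    """Compute p_t = accuracy / median(ln rt_ms) for one session.

    Response times are floored at ``RT_FLOOR_MS`` before the log so the
    median is strictly positive.  An even number of trials uses the mean of
    the two central order statistics.
    """
    results = record.results if isinstance(record, SessionRecord) else list(record)
    if len(results) == 0:
        raise ValueError("cannot compute a performance index for an empty session")
    rt = np.array([r.rt_ms for r in results], dtype=float)
    if np.any(rt <= 0) or not np.all(np.isfinite(rt)):
        raise ValueError("all response times must be finite and positive")
    correct = np.array([r.correct for r in results], dtype=float)
    accuracy = float(correct.mean())
    median_log_rt = float(np.median(np.log(np.maximum(rt, RT_FLOOR_MS))))
    return PerformanceIndex(
        value=accuracy / median_log_rt,
        accuracy=accuracy,
        median_log_rt=median_log_rt,
    )


def rolling_itr_sd(itr_history: Sequence[float], k: int = DEFAULT_SD_WINDOW) -> float:
    """Sample SD (divisor ``k - 1``) of the last ``k`` ITRs in the history."""
    if k < 2:
        raise ValueError(f"window k must be >= 2, got {k}")
    if len(itr_history) < k:
        raise InsufficientHistoryError(
            f"need at least {k} sessions for a rolling SD, got {len(itr_history)}"
        )
    window = np.asarray(itr_history[-k:], dtype=float)
    return float(np.std(window, ddof=1))


def difficulty_features(
    itr_history: Sequence[float], k: int = DEFAULT_SD_WINDOW
) -> DifficultyFeatures:
    """Difficulty features (ITR, ITR², rolling SD) for the latest session."""
    if len(itr_history) == 0:
        raise ValueError("itr_history must be nonempty")
    itr = float(itr_history[-1])
    sd = rolling_itr_sd(itr_history, k) if len(itr_history) >= k else None
    return DifficultyFeatures(itr=itr, itr_sq=itr * itr, itr_sd_k=sd, k=k)


def session_metrics(
    records: dict[str, Sequence[SessionRecord]] | Sequence[SessionRecord],
    k: int = DEFAULT_SD_WINDOW,
    subject_id: str = "s01",
) -> pd.DataFrame:
    """Per-session metrics table for one or many subjects.

    Columns: subject_id, session_index, itr, itr_sq, itr_sd_k (NaN while the
    history is shorter than ``k``), accuracy, median_log_rt, performance.
    This is the input schema of the retrospective mixed-model analysis.
    """
    if not isinstance(records, dict):
        records = {subject_id: records}
    rows = []
    for subj, sessions in records.items():
        ordered = sorted(sessions, key=lambda r: r.plan.session_index)
        history: list[float] = []
        for rec in ordered:
            history.append(rec.plan.itr)
            feats = difficulty_features(history, k)
            perf = performance_index(rec)
            rec.performance = perf.value
            rows.append(
                (
                    subj,
                    rec.plan.session_index,
                    feats.itr,
                    feats.itr_sq,
                    math.nan if feats.itr_sd_k is None else feats.itr_sd_k,
                    perf.accuracy,
                    perf.median_log_rt,
                    perf.value,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "session_index",
            "itr",
            "itr_sq",
            "itr_sd_k",
            "accuracy",
            "median_log_rt",
            "performance",
        ],
    )
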