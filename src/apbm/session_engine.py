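"""Construction and serialization of ApBM training sessions.

An approach-bias-modification (ApBM) session is an ordered list of trials.
Each trial shows either a drug-related or a healthy-living image in one of
two orientations; the orientation tells the participant which swipe action
is required (by default portrait = avoid/push, landscape = approach/pull).
A trial is *congruent* when the required action matches the therapeutic
intention: avoiding drug cues or approaching healthy cues.

The intended training ratio (ITR) of a session is the fraction of congruent
trials.  The static training arm uses a fixed ITR of 144/156 ~ 92.3%; the
adaptive arm varies the ITR between sessions under an online controller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Category",
    "Orientation",
    "Action",
    "TrialSpec",
    "SessionPlan",
    "TrialResult",
    "SessionRecord",
    "STATIC_N_TRIALS",
    "STATIC_CONGRUENT",
    "STATIC_ITR",
    "is_congruent",
    "build_session",
    "static_plan",
    "write_log",
    "read_log",
]


class Category(str, Enum):
    DRUG = "drug"
    HEALTHY = "healthy"


class Orientation(str, Enum):
    PORTRAIT = "portrait"
    LANDSCAPE = "landscape"


class Action(str, Enum):
    AVOID = "avoid"
    APPROACH = "approach"


#: Trials per session and congruent count of the static (S-ApBM) arm.
STATIC_N_TRIALS = 156
STATIC_CONGRUENT = 144
STATIC_ITR = STATIC_CONGRUENT / STATIC_N_TRIALS

LOG_COLUMNS = [
    "subject_id",
    "session_index",
    "trial_index",
    "category",
    "orientation",
    "congruent",
    "correct",
    "rt_ms",
]


def is_congruent(category: Category, action: Action) -> bool:
    """A trial is congruent when a drug cue is avoided or a healthy cue approached."""
    return (category == Category.DRUG and action == Action.AVOID) or (
        category == Category.HEALTHY and action == Action.APPROACH
    )


@dataclass(frozen=True)
class TrialSpec:
    """A single planned trial."""

    index: int
    category: Category
    orientation: Orientation
    congruent: bool
    required_action: Action

    def __post_init__(self) -> None:
        if self.congruent != is_congruent(self.category, self.required_action):
            raise ValueError(
                f"trial {self.index}: congruency flag inconsistent with "
                f"category={self.category.value}, action={self.required_action.value}"
            )


@dataclass
class SessionPlan:
    """An ordered trial list realizing a requested ITR at session index ``t``.

    ``itr`` stores the *realized* ratio (congruent count / n_trials) after
    integer rounding, so it is always an exact multiple of ``1/n_trials``.
    """

    session_index: int
    n_trials: int
    itr: float
    trials: list[TrialSpec] = field(repr=False)
    seed: int | None = None

    @property
    def n_congruent(self) -> int:
        return sum(tr.congruent for tr in self.trials)


@dataclass(frozen=True)
class TrialResult:
    """Observed outcome of one trial: correctness and response time (ms)."""

    index: int
    correct: bool
    rt_ms: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.rt_ms) and self.rt_ms > 0):
            raise ValueError(f"trial {self.index}: rt_ms must be finite and positive")


@dataclass
class SessionRecord:
    """A completed session: plan, per-trial results and the derived performance index."""

    plan: SessionPlan
    results: list[TrialResult] = field(repr=False)
    performance: float | None = None

    def __post_init__(self) -> None:
        if len(self.results) != len(self.plan.trials):
            raise ValueError(
                f"session {self.plan.session_index}: {len(self.results)} results "
                f"for {len(self.plan.trials)} trials"
            )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def build_session(
    itr: float,
    n_trials: int,
    t: int = 1,
    seed: int | None = 0,
    portrait_action: Action = Action.AVOID,
) -> SessionPlan:
    """Build a session whose congruent count is ``round_half_up(itr * n_trials)``.

    Categories are split as evenly as possible (drug gets ``n_trials // 2``)
    and the congruent trials are allocated to the two categories
    proportionally.  The orientation of each trial deterministically encodes
    its required action through ``portrait_action``; trial order is a seeded
    uniform shuffle.

    Parameters
    ----------
    itr:
        Requested intended training ratio in [0, 1].
    n_trials:
        Number of trials, at least 2.
    t:
        1-based session index stored on the plan.
    seed:
        Seed of the shuffle; ``None`` keeps the deterministic blocked order.
    """
    if not (isinstance(itr, (int, float)) and math.isfinite(itr)):
        raise ValueError("itr must be a finite number")
    if not 0.0 <= itr <= 1.0:
        raise ValueError(f"itr must lie in [0, 1], got {itr!r}")
    if n_trials < 2:
        raise ValueError(f"n_trials must be >= 2, got {n_trials}")
    if t < 1:
        raise ValueError(f"session index must be >= 1, got {t}")

    n_congruent = _round_half_up(itr * n_trials)
    n_drug = n_trials // 2
    n_healthy = n_trials - n_drug

    # allocate congruent trials to categories proportionally
    c_drug = min(_round_half_up(n_congruent * n_drug / n_trials), n_drug)
    c_healthy = n_congruent - c_drug
    if c_healthy > n_healthy:  # rebalance at the boundary
        c_drug += c_healthy - n_healthy
        c_healthy = n_healthy

    landscape_action = (
        Action.APPROACH if portrait_action == Action.AVOID else Action.AVOID
    )
    orient_of = {
        portrait_action: Orientation.PORTRAIT,
        landscape_action: Orientation.LANDSCAPE,
    }

    def make(category: Category, congruent: bool, count: int) -> list[tuple]:
        if category == Category.DRUG:
            action = Action.AVOID if congruent else Action.APPROACH
        else:
            action = Action.APPROACH if congruent else Action.AVOID
        return [(category, orient_of[action], congruent, action)] * count

    blocks = (
        make(Category.DRUG, True, c_drug)
        + make(Category.DRUG, False, n_drug - c_drug)
        + make(Category.HEALTHY, True, c_healthy)
        + make(Category.HEALTHY, False, n_healthy - c_healthy)
    )
    order = np.arange(n_trials)
    if seed is not None:
        order = np.random.default_rng(seed).permutation(n_trials)
    trials = [
        TrialSpec(i + 1, *blocks[j]) for i, j in enumerate(order)
    ]
    return SessionPlan(
        session_index=t,
        n_trials=n_trials,
        itr=n_congruent / n_trials,
        trials=trials,
        seed=seed,
    )


def static_plan(t: int, seed: int | None = 0) -> SessionPlan:
    """The static (S-ApBM) arm session: 144 congruent of 156 trials (ITR 92.3%)."""
    return build_session(STATIC_ITR, STATIC_N_TRIALS, t=t, seed=seed)


def _records_to_frame(records: Iterable[SessionRecord], subject_id: str) -> pd.DataFrame:
    rows = []
    for rec in records:
        for tr, res in zip(rec.plan.trials, rec.results):
            rows.append(
                (
                    subject_id,
                    rec.plan.session_index,
                    tr.index,
                    tr.category.value,
                    tr.orientation.value,
                    int(tr.congruent),
                    int(res.correct),
                    float(res.rt_ms),
                )
            )
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def write_log(
    records: dict[str, Sequence[SessionRecord]] | Sequence[SessionRecord],
    path,
    subject_id: str = "s01",
) -> pd.DataFrame:
    """Write session records to a per-trial CSV log (one row per trial).

    ``records`` is either a mapping ``subject_id -> sessions`` or a plain
    sequence of sessions attributed to ``subject_id``.  Returns the frame
    that was written.
    """
    if isinstance(records, dict):
        frames = [_records_to_frame(v, k) for k, v in records.items()]
        df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=LOG_COLUMNS)
    else:
        df = _records_to_frame(records, subject_id)
    df.to_csv(path, index=False)
    return df


def _action_from(category: Category, congruent: bool) -> Action:
    if category == Category.DRUG:
        return Action.AVOID if congruent else Action.APPROACH
    return Action.APPROACH if congruent else Action.AVOID


def read_log(path) -> dict[str, list[SessionRecord]]:
    """Parse a session-log CSV back into per-subject ``SessionRecord`` lists.

    Rows violating the schema (e.g. non-positive response time) are rejected
    with an error naming the offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"session log missing columns: {missing}")

    bad = df.index[~(df["rt_ms"] > 0) | ~np.isfinite(df["rt_ms"])]
    if len(bad):
        # +2: 1-based data rows after the header line
        raise ValueError(f"non-positive rt_ms in CSV row {bad[0] + 2}")

    out: dict[str, list[SessionRecord]] = {}
    for (subj, sess), grp in df.groupby(["subject_id", "session_index"], sort=True):
        grp = grp.sort_values("trial_index")
        trials, results = [], []
        for row in grp.itertuples(index=False):
            category = Category(row.category)
            congruent = bool(row.congruent)
            trials.append(
                TrialSpec(
                    index=int(row.trial_index),
                    category=category,
                    orientation=Orientation(row.orientation),
                    congruent=congruent,
                    required_action=_action_from(category, congruent),
                )
            )
            results.append(
                TrialResult(int(row.trial_index), bool(row.correct), float(row.rt_ms))
            )
        n = len(trials)
        plan = SessionPlan(
            session_index=int(sess),
            n_trials=n,
            itr=sum(tr.congruent for tr in trials) / n,
            trials=trials,
            seed=None,
        )
        out.setdefault(str(subj), []).append(SessionRecord(plan, results))
    return out
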