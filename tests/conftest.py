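import math

import numpy as np
import pandas as pd
import pytest

from apbm.session_engine import SessionRecord, TrialResult, build_session
from apbm.trial_analysis import GROUPS, TIMEPOINTS


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


def make_record(correct, rts, itr=0.8, t=1, seed=0):
    """A SessionRecord with prescribed correctness flags and RTs (ms)."""
    n = len(correct)
    plan = build_session(itr, n, t=t, seed=seed)
    results = [
        TrialResult(i + 1, bool(c), float(r)) for i, (c, r) in enumerate(zip(correct, rts))
    ]
    return SessionRecord(plan, results)


def craving_frame(scores_by_group):
    """Long craving table from {group: ndarray (n_subjects, 3)} blocks."""
    rows = []
    counter = 0
    for g in GROUPS:
        if g not in scores_by_group:
            continue
        block = np.asarray(scores_by_group[g], dtype=float)
        for i in range(block.shape[0]):
            counter += 1
            for ti, tp in enumerate(TIMEPOINTS):
                if not math.isnan(block[i, ti]):
                    rows.append((f"p{counter:03d}", g, tp, block[i, ti]))
    return pd.DataFrame(rows, columns=["subject_id", "group", "timepoint", "score"])


@pytest.fixture
def balanced_craving(rng):
    """Balanced 3x4 subjects craving table with correlated timepoints."""
    blocks = {}
    for gi, g in enumerate(GROUPS):
        base = rng.gamma(2.0, 5.0, size=4)
        noise = rng.normal(0, 2.0, size=(4, 3))
        blocks[g] = np.clip(base[:, None] + gi * noise, 0, 100)
    return craving_frame(blocks)
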