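"""Online per-user difficulty controller for adaptive ApBM training.

The loop: three warm-up sessions at a fixed ITR, then after each completed
session an ordinary-least-squares fit of the session performance index on
the difficulty features and a quadratic time trend,

    p_t ~ g0 + g_itr*ITR + g_itr2*ITR**2 + g_sd*SD_k + g_t*t + g_t2*t**2,

whose ITR-dependent part is the controller's working estimate of how
difficult a candidate session would feel.  The weights on the difficulty
features absorb the product of the performance-difficulty slope with the
difficulty-model weights; the two sets are not separately identifiable from
a single regression, and the controller never needs them separately: the
selection rule only uses the *ordering* of predicted difficulty over the
feasible ITR grid, which is invariant to the affine normalization applied
here.  The next session's ITR is the feasible congruent count whose
normalized predicted difficulty is closest to a predetermined target curve
(an inverted U by default: challenge ramps to a mid-program peak, then
tapers).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from enum import Enum


import numpy as np
import pandas as pd

from .metrics import DEFAULT_SD_WINDOW, performance_index
from .session_engine import STATIC_ITR, SessionRecord, build_session

__all__ = [
    "CurveShape",
    "DifficultyCurve",
    "CompositeCoefficients",
    "ControllerConfig",
    "ControllerState",
    "target_curve",
    "fit_user_model",
    "predicted_difficulty",
    "select_next_itr",
    "run_loop",
    "LoopResult",
]


class CurveShape(str, Enum):
    U = "U"
    INVERTED_U = "inverted_U"
    N = "N"
    INVERTED_N = "inverted_N"


@dataclass(frozen=True)
class DifficultyCurve:
    """Target normalized difficulty d*(t) on the session grid t = 1..T."""

    shape: CurveShape
    T: int
    d_lo: float
    d_hi: float
    values: np.ndarray = field(repr=False)

    def target(self, t: int) -> float:
        if not 1 <= t <= self.T:
            raise ValueError(f"session index {t} outside 1..{self.T}")
        return float(self.values[t - 1])


def target_curve(
    shape: CurveShape | str,
    T: int,
    d_lo: float = 0.15,
    d_hi: float = 0.85,
) -> DifficultyCurve:
    """Evaluate one of the four canonical difficulty curves on t = 1..T.

    On the standardized time u = (2t - 1 - T)/(T - 1) in [-1, 1]:

    - ``inverted_U``: d_lo + (d_hi - d_lo) * (1 - u^2), peaking mid-program;
    - ``U``: its reflection d_lo + (d_hi - d_lo) * u^2;
    - ``N`` / ``inverted_N``: the cubic +-(2u^3 - u) rescaled to [d_lo, d_hi].
    """
    shape = CurveShape(shape)
    if T < 3:
        raise ValueError(f"T must be >= 3, got {T}")
    if not (0.0 <= d_lo < d_hi <= 1.0):
        raise ValueError(f"need 0 <= d_lo < d_hi <= 1, got ({d_lo}, {d_hi})")
    t = np.arange(1, T + 1, dtype=float)
    u = (2.0 * t - 1.0 - T) / (T - 1.0)
    span = d_hi - d_lo
    if shape == CurveShape.INVERTED_U:
        vals = d_lo + span * (1.0 - u * u)
    elif shape == CurveShape.U:
        vals = d_lo + span * u * u
    else:
        f = 2.0 * u**3 - u  # N-shape on [-1, 1], range [-1, 1]
        if shape == CurveShape.INVERTED_N:
            f = -f
        vals = d_lo + span * (f + 1.0) / 2.0
    return DifficultyCurve(shape=shape, T=T, d_lo=d_lo, d_hi=d_hi, values=vals)


@dataclass(frozen=True)
class CompositeCoefficients:
    """OLS weights of the per-user performance model (composite estimands)."""

    g0: float
    g_itr: float
    g_itr2: float
    g_sd: float
    g_t: float
    g_t2: float
    resid_var: float
    dropped: tuple[str, ...] = ()

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=list)


@dataclass
class ControllerConfig:
    """Tunables of the adaptive loop (all surfaced, defaults as shipped)."""

    n_trials: int = 156
    warmup_sessions: int = 3
    warmup_itr: float = STATIC_ITR
    total_sessions: int = 28
    curve_shape: CurveShape = CurveShape.INVERTED_U
    d_lo: float = 0.15
    d_hi: float = 0.85
    itr_min: float = 0.5
    itr_max: float = 1.0
    sd_window: int = DEFAULT_SD_WINDOW
    standardize_performance: bool = False
    schedule_seed: int = 0

    def __post_init__(self) -> None:
        self.curve_shape = CurveShape(self.curve_shape)
        if not (0.0 <= self.itr_min < self.itr_max <= 1.0):
            raise ValueError("need 0 <= itr_min < itr_max <= 1")
        if not (self.itr_min <= self.warmup_itr <= self.itr_max):
            raise ValueError("warmup_itr must lie within [itr_min, itr_max]")

    def congruent_grid(self) -> np.ndarray:
        lo = math.ceil(self.itr_min * self.n_trials)
        hi = math.floor(self.itr_max * self.n_trials)
        if hi < lo:
            raise ValueError("empty congruent-count grid: itr bounds too tight")
        return np.arange(lo, hi + 1)


@dataclass
class ControllerState:
    """Cumulative per-user history and the current fitted model."""

    subject_id: str
    config: ControllerConfig = field(default_factory=ControllerConfig)
    curve: DifficultyCurve | None = None
    history: list[tuple[int, float, float, float]] = field(default_factory=list)
    #: (t, itr, sd_k with 0 imputed while t < k, performance)
    coefficients: CompositeCoefficients | None = None

    def __post_init__(self) -> None:
        if self.curve is None:
            self.curve = target_curve(
                self.config.curve_shape,
                self.config.total_sessions,
                self.config.d_lo,
                self.config.d_hi,
            )

    @property
    def itr_history(self) -> list[float]:
        return [h[1] for h in self.history]

    def record(self, t: int, itr: float, performance: float) -> None:
        if self.history and t <= self.history[-1][0]:
            raise ValueError("session indices must be strictly increasing")
        k = self.config.sd_window
        itrs = self.itr_history + [itr]
        sd = float(np.std(itrs[-k:], ddof=1)) if len(itrs) >= k else 0.0
        self.history.append((t, itr, sd, performance))


_FEATURES = ("const", "itr", "itr_sq", "sd", "t", "t_sq")
_DROP_PRIORITY = ("itr_sq", "sd", "itr")


def fit_user_model(state: ControllerState) -> CompositeCoefficients | None:
    """OLS of performance on {1, ITR, ITR², SD_k, t, t²} over all sessions.

    The rolling SD is imputed as 0 for sessions before the window fills, so
    every row participates.  Collinear columns are pruned in the fixed order
    ITR² -> SD_k -> ITR (e.g. a constant-ITR history makes ITR and ITR²
    multiples of the intercept); pruned terms get weight 0 and are reported
    in ``dropped``.  Returns ``None`` (coefficients absent) before the first
    post-warm-up session or if the design stays rank-deficient.
    """
    cfg = state.config
    n = len(state.history)
    if n < cfg.warmup_sessions + 1:
        return None
    t = np.array([h[0] for h in state.history], dtype=float)
    itr = np.array([h[1] for h in state.history], dtype=float)
    sd = np.array([h[2] for h in state.history], dtype=float)
    p = np.array([h[3] for h in state.history], dtype=float)
    if cfg.standardize_performance and p.std() > 0:
        p = (p - p.mean()) / p.std()
    cols = {
        "const": np.ones(n),
        "itr": itr,
        "itr_sq": itr * itr,
        "sd": sd,
        "t": t,
        "t_sq": t * t,
    }
    kept = list(_FEATURES)
    dropped: list[str] = []
    for name in _DROP_PRIORITY:
        X = np.column_stack([cols[c] for c in kept])
        if np.linalg.matrix_rank(X, tol=1e-8) == len(kept) and len(kept) <= n:
            break
        kept.remove(name)
        dropped.append(name)
    X = np.column_stack([cols[c] for c in kept])
    if np.linalg.matrix_rank(X, tol=1e-8) < len(kept) or len(kept) > n:
        return None
    beta, *_ = np.linalg.lstsq(X, p, rcond=None)
    resid = p - X @ beta
    dof = n - len(kept)
    resid_var = float(resid @ resid / dof) if dof > 0 else 0.0
    g = dict.fromkeys(_FEATURES, 0.0)
    g.update(zip(kept, map(float, beta)))
    return CompositeCoefficients(
        g0=g["const"],
        g_itr=g["itr"],
        g_itr2=g["itr_sq"],
        g_sd=g["sd"],
        g_t=g["t"],
        g_t2=g["t_sq"],
        resid_var=resid_var,
        dropped=tuple(dropped),
    )


def _raw_difficulty(coef: CompositeCoefficients, itr: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Raw (unnormalized) difficulty reconstruction.

    The fitted weights are the ITR-dependent part of *predicted
    performance*; since the difficulty construct is defined to depress
    performance (negative difficulty->performance slope), difficulty is its
    negated affine image.  The sign matters: a positive-scale normalization
    cannot flip orientation afterwards.
    """
    return -(coef.g_itr * itr + coef.g_itr2 * itr * itr + coef.g_sd * sd)


def _normalize(values: np.ndarray) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi - lo < 1e-12:
        return np.full_like(values, 0.5)
    return (values - lo) / (hi - lo)


def predicted_difficulty(
    coef: CompositeCoefficients,
    itr: float | np.ndarray,
    sd_k: float = 0.0,
    itr_min: float = 0.5,
    itr_max: float = 1.0,
    n_trials: int = 156,
) -> np.ndarray | float:
    """Normalized predicted difficulty of ``itr`` at the current rolling SD.

    The raw prediction ``g_itr*ITR + g_itr2*ITR² + g_sd*SD`` is affinely
    mapped to [0, 1] over the feasible congruent-count grid (constant 0.5
    when the ITR-dependent part is flat, e.g. all three weights zero).
    """
    lo = math.ceil(itr_min * n_trials)
    hi = math.floor(itr_max * n_trials)
    grid = np.arange(lo, hi + 1) / n_trials
    raw_grid = _raw_difficulty(coef, grid, np.full_like(grid, sd_k))
    g_lo, g_hi = float(raw_grid.min()), float(raw_grid.max())
    itr_arr = np.asarray(itr, dtype=float)
    raw = _raw_difficulty(coef, itr_arr, np.full_like(itr_arr, sd_k))
    if g_hi - g_lo < 1e-12:
        out = np.full_like(itr_arr, 0.5)
    else:
        out = (raw - g_lo) / (g_hi - g_lo)
    return float(out) if np.isscalar(itr) else out


def select_next_itr(state: ControllerState, t_next: int) -> tuple[float, int]:
    """Choose the next session's (ITR, congruent count).

    During warm-up (and whenever coefficients are absent) the warm-up ITR is
    returned unchanged.  Otherwise every feasible congruent count ``c`` is a
    candidate: its rolling SD *including the candidate* is computed, the raw
    predicted difficulty over all candidates is affinely normalized to
    [0, 1], and the candidate closest to the target d*(t_next) wins, ties
    going to the larger count (the more conservative, more congruent
    session).
    """
    if t_next < 1:
        raise ValueError("t_next must be >= 1")
    cfg = state.config
    warm_c = int(round(cfg.warmup_itr * cfg.n_trials))
    warm = (warm_c / cfg.n_trials, warm_c)
    if t_next <= cfg.warmup_sessions or state.coefficients is None:
        return warm
    coef = state.coefficients
    grid_c = cfg.congruent_grid()
    cand_itr = grid_c / cfg.n_trials
    k = cfg.sd_window
    past = state.itr_history[-(k - 1):] if k >= 2 else []
    if len(past) == k - 1:
        windows = np.column_stack(
            [np.tile(past, (cand_itr.size, 1)), cand_itr]
        )
        cand_sd = np.std(windows, axis=1, ddof=1)
    else:
        cand_sd = np.zeros_like(cand_itr)
    norm = _normalize(_raw_difficulty(coef, cand_itr, cand_sd))
    d_star = state.curve.target(t_next)
    err = np.abs(norm - d_star)
    best = err.min()
    # ties (within float tolerance) break toward the larger congruent count
    idx = int(np.flatnonzero(err <= best + 1e-12)[-1])
    return float(cand_itr[idx]), int(grid_c[idx])


@dataclass
class LoopResult:
    """Closed-loop output: per-session records, trace table, final state."""

    records: list[SessionRecord]
    trace: pd.DataFrame
    state: ControllerState
    error: str | None = None


def run_loop(
    participant,
    config: ControllerConfig | None = None,
    subject_id: str = "sim",
    adaptive: bool = True,
) -> LoopResult:
    """Run the full training program against a participant.

    ``participant`` is any object with ``respond(plan, t) -> list[TrialResult]``
    (a :class:`~apbm.virtual_participant.VirtualParticipant`, or a replayer
    over recorded logs).  With ``adaptive=False`` the warm-up ITR is held for
    the whole program — the static arm.  Fully deterministic given the
    schedule seed and the participant's own RNG state.  If the participant
    raises mid-loop, the partial trace is returned with the error recorded.
    """
    cfg = config or ControllerConfig()
    state = ControllerState(subject_id=subject_id, config=cfg)
    records: list[SessionRecord] = []
    rows = []
    error = None
    for t in range(1, cfg.total_sessions + 1):
        if adaptive:
            itr_t, _ = select_next_itr(state, t)
        else:
            itr_t = int(round(cfg.warmup_itr * cfg.n_trials)) / cfg.n_trials
        plan = build_session(
            itr_t, cfg.n_trials, t=t, seed=cfg.schedule_seed + 7919 * t
        )
        try:
            results = participant.respond(plan, t)
        except Exception as exc:  # pragma: no cover - participant failure path
            error = f"participant failed at session {t}: {exc}"
            break
        perf = performance_index(results)
        records.append(SessionRecord(plan, results, performance=perf.value))
        state.record(t, plan.itr, perf.value)
        coef = state.coefficients
        d_pred = math.nan
        if coef is not None:
            d_pred = float(
                predicted_difficulty(
                    coef,
                    plan.itr,
                    sd_k=state.history[-1][2],
                    itr_min=cfg.itr_min,
                    itr_max=cfg.itr_max,
                    n_trials=cfg.n_trials,
                )
            )
        rows.append(
            (
                subject_id,
                t,
                plan.itr,
                state.curve.target(t),
                d_pred,
                perf.value,
                coef.to_json() if coef is not None else "",
            )
        )
        if adaptive and t >= cfg.warmup_sessions + 1:
            state.coefficients = fit_user_model(state)
    trace = pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "t",
            "itr_selected",
            "d_target",
            "d_predicted",
            "performance",
            "coefficients",
        ],
    )
    return LoopResult(records=records, trace=trace, state=state, error=error)
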