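"""Generative model of an ApBM trainee.

Session-level performance follows a per-user linear model

    p_t = b0_i + b1 * d_t + b2 * t + b3 * t**2 + eps_t,    eps_t ~ N(0, sigma**2),

where ``d_t`` is the latent session difficulty and ``b0_i`` a subject
random intercept.  The latent difficulty is a quadratic function of the
session ITR plus a term in the rolling SD of recent ITRs,

    d_t = alpha0 + alpha1 * ITR_t**2 + alpha2 * SD(ITR_{t-k+1..t}),

with ``alpha1 < 0`` so that difficulty peaks toward ITR = 0.5 (maximum
stimulus-action unpredictability) and declines as the session becomes all
congruent.

The paper-level model stops at the session summary; the trial-level bridge
here (Bernoulli correctness split by congruency, log-normal response times)
is this package's own construction, built so that the session summary is an
unbiased realization of the requested ``p_t``: response times are drawn with
log-median ``L`` and the overall accuracy target is ``A = clamp(p_t * L, 0, 1)``,
so accuracy / median-log-RT recovers ``p_t`` in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .session_engine import SessionPlan, TrialResult, build_session
from .metrics import DEFAULT_SD_WINDOW, RT_FLOOR_MS

__all__ = [
    "ParticipantModel",
    "CohortSpec",
    "VirtualParticipant",
    "session_performance",
    "simulate_session",
    "simulate_cohort",
    "random_schedule",
]


@dataclass(frozen=True)
class ParticipantModel:
    """Generative parameters of one virtual trainee.

    Defaults keep p_t inside (0, 1/L) for ITRs in [0.5, 1] over a 28-session
    program: baseline p ~ 0.10, a mild negative difficulty slope, a slow
    positive learning trend, and small session noise.
    """

    b0i: float = 0.10          # subject intercept (performance-index units)
    b1: float = -0.02          # difficulty -> performance slope
    b2: float = 0.0015         # linear learning trend per session
    b3: float = -2e-5          # quadratic learning term
    sigma: float = 0.005       # SD of the idiosyncratic session noise
    alpha0: float = 4.0 / 3.0  # difficulty intercept
    alpha1: float = -4.0 / 3.0 # ITR^2 weight (negative: all-congruent is easiest)
    alpha2: float = 0.5        # rolling-SD weight (variability adds difficulty)
    incong_penalty: float = 0.05  # accuracy decrement on incongruent trials
    rt_log_median: float = 7.0    # median of ln(RT in ms); e^7 ~ 1097 ms
    rt_log_sd: float = 0.2        # spread of ln(RT)

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.incong_penalty <= 1.0:
            raise ValueError("incong_penalty must lie in [0, 1]")

    def difficulty(self, itr: float, itr_sd: float = 0.0) -> float:
        """Latent difficulty d_t = alpha0 + alpha1*ITR^2 + alpha2*SD."""
        return self.alpha0 + self.alpha1 * itr * itr + self.alpha2 * itr_sd

    def normalized_difficulty(self, itr, itr_min: float = 0.5, itr_max: float = 1.0):
        """ITR-driven difficulty affinely mapped to [0, 1] over [itr_min, itr_max].

        The rolling-SD term is constant across an ITR grid at fixed history,
        so it cancels under the affine normalization and only the quadratic
        ITR part matters.
        """
        itr = np.asarray(itr, dtype=float)
        f = self.alpha1 * itr * itr
        f_ends = self.alpha1 * np.array([itr_min, itr_max]) ** 2
        lo, hi = float(f_ends.min()), float(f_ends.max())
        if hi - lo < 1e-12:
            return np.full_like(itr, 0.5)
        return (f - lo) / (hi - lo)


def session_performance(
    model: ParticipantModel, d_t: float, t: int, rng: np.random.Generator | None = None
) -> float:
    """One draw of p_t = b0i + b1*d_t + b2*t + b3*t^2 + N(0, sigma^2)."""
    if t < 1:
        raise ValueError("session index t must be >= 1")
    noise = 0.0
    if rng is not None and model.sigma > 0:
        noise = float(rng.normal(0.0, model.sigma))
    return model.b0i + model.b1 * d_t + model.b2 * t + model.b3 * t * t + noise


def _accuracy_split(model: ParticipantModel, itr: float, A: float) -> tuple[float, float]:
    """Congruent/incongruent accuracy targets whose ITR-mixture equals ``A``.

    The incongruent accuracy sits ``incong_penalty`` below the congruent one
    where feasible; at the boundaries the split is clamped to [0, 1] (which
    may shrink the effective penalty) while preserving the mixture as far as
    possible.
    """
    pen = model.incong_penalty
    a_c = min(1.0, A + (1.0 - itr) * pen)
    if itr < 1.0:
        a_i = (A - itr * a_c) / (1.0 - itr)
        if a_i < 0.0:
            a_i = 0.0
            a_c = min(1.0, A / itr) if itr > 0 else 0.0
    else:
        a_i = max(0.0, a_c - pen)
    return a_c, a_i


def _simulate_session_arrays(
    model: ParticipantModel,
    congruent: np.ndarray,
    p_target: float,
    rng: np.random.Generator,
    deterministic: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized trial draws: (correct bool array, rt_ms array)."""
    n = congruent.size
    L = model.rt_log_median
    A = min(max(p_target * L, 0.0), 1.0)
    itr = float(congruent.mean())
    a_c, a_i = _accuracy_split(model, itr, A)
    p_trial = np.where(congruent, a_c, a_i)
    if deterministic:
        # realize expected counts exactly, constant RTs at the log-median
        correct = np.zeros(n, dtype=bool)
        for mask, a in ((congruent, a_c), (~congruent, a_i)):
            idx = np.flatnonzero(mask)
            n_corr = int(round(a * idx.size))
            correct[idx[:n_corr]] = True
        rt = np.full(n, math.exp(L))
    else:
        correct = rng.random(n) < p_trial
        rt = np.exp(rng.normal(L, model.rt_log_sd, size=n))
    rt = np.maximum(rt, RT_FLOOR_MS)
    return correct, rt


def simulate_session(
    model: ParticipantModel,
    plan: SessionPlan,
    p_target: float,
    rng: np.random.Generator | int | None = None,
    deterministic: bool = False,
) -> list[TrialResult]:
    """Realize trial results whose session summary targets ``p_target``.

    With ``deterministic=True`` the expected correct counts are realized
    exactly and all RTs sit at the log-median, removing trial-level noise
    (useful for low-noise closed-loop tests).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    congruent = np.array([tr.congruent for tr in plan.trials], dtype=bool)
    correct, rt = _simulate_session_arrays(model, congruent, p_target, rng, deterministic)
    return [
        TrialResult(tr.index, bool(c), float(r))
        for tr, c, r in zip(plan.trials, correct, rt)
    ]


class VirtualParticipant:
    """Stateful trainee for closed-loop runs.

    Tracks the ITRs it has actually been given, derives the latent
    difficulty of each new session from its own model, draws a session
    performance, and realizes trial results consistent with it.
    """

    def __init__(
        self,
        model: ParticipantModel | None = None,
        rng: np.random.Generator | int | None = None,
        sd_window: int = DEFAULT_SD_WINDOW,
        deterministic_trials: bool = False,
    ) -> None:
        self.model = model or ParticipantModel()
        self.rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self.sd_window = sd_window
        self.deterministic_trials = deterministic_trials
        self.itr_history: list[float] = []

    def respond(self, plan: SessionPlan, t: int) -> list[TrialResult]:
        self.itr_history.append(plan.itr)
        k = self.sd_window
        sd = (
            float(np.std(self.itr_history[-k:], ddof=1))
            if len(self.itr_history) >= k
            else 0.0
        )
        d = self.model.difficulty(plan.itr, sd)
        p = session_performance(self.model, d, t, self.rng)
        return simulate_session(
            self.model, plan, p, self.rng, deterministic=self.deterministic_trials
        )


@dataclass(frozen=True)
class CohortSpec:
    """Hyperparameters of a simulated cohort: shared slopes, random intercepts."""

    n_subjects: int = 50
    mu0: float = 0.10   # mean of the subject intercepts
    tau: float = 0.01   # SD of the subject intercepts
    base: ParticipantModel = field(default_factory=ParticipantModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")

    def draw_models(self, rng: np.random.Generator) -> list[ParticipantModel]:
        b0 = rng.normal(self.mu0, self.tau, size=self.n_subjects)
        return [replace(self.base, b0i=float(b)) for b in b0]


def random_schedule(
    n_sessions: int,
    rng: np.random.Generator,
    itr_min: float = 0.5,
    itr_max: float = 1.0,
    n_trials: int = 156,
) -> np.ndarray:
    """Uniform random per-session ITRs on the feasible congruent-count grid."""
    lo = math.ceil(itr_min * n_trials)
    hi = math.floor(itr_max * n_trials)
    return rng.integers(lo, hi + 1, size=n_sessions) / n_trials


def simulate_cohort(
    spec: CohortSpec,
    schedule: Sequence[float] | Callable[[np.random.Generator], np.ndarray],
    n_trials: int = 156,
    sd_window: int = DEFAULT_SD_WINDOW,
    detail: str = "sessions",
    plan_seed_base: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an open-loop cohort on a fixed or per-subject ITR schedule.

    ``schedule`` is either a shared per-session ITR sequence or a callable
    drawing one per subject.  Returns ``(data, truth)``: with
    ``detail="sessions"`` the data frame holds one row per session in the
    session-metrics schema (performance computed from vectorized trial
    draws); with ``detail="trials"`` it is the per-trial session-log schema.
    ``truth`` records each subject's intercept and the shared slopes.
    """
    if detail not in ("sessions", "trials"):
        raise ValueError("detail must be 'sessions' or 'trials'")
    rng = np.random.default_rng(spec.seed)
    models = spec.draw_models(rng)
    rows = []
    trial_rows = []
    for si, model in enumerate(models):
        subj = f"s{si + 1:03d}"
        itrs = np.asarray(schedule(rng) if callable(schedule) else schedule, dtype=float)
        history: list[float] = []
        for ti, itr_req in enumerate(itrs, start=1):
            n_cong = int(round(itr_req * n_trials))
            itr = n_cong / n_trials
            history.append(itr)
            sd = (
                float(np.std(history[-sd_window:], ddof=1))
                if len(history) >= sd_window
                else 0.0
            )
            d = model.difficulty(itr, sd)
            p = session_performance(model, d, ti, rng)
            if detail == "trials":
                plan = build_session(itr, n_trials, ti, seed=plan_seed_base + 1000 * si + ti)
                congruent = np.array([tr.congruent for tr in plan.trials])
            else:
                plan = None
                congruent = np.zeros(n_trials, dtype=bool)
                congruent[:n_cong] = True
            correct, rt = _simulate_session_arrays(model, congruent, p, rng)
            accuracy = float(correct.mean())
            med = float(np.median(np.log(rt)))
            sd_out = sd if len(history) >= sd_window else math.nan
            rows.append((subj, ti, itr, itr * itr, sd_out, accuracy, med, accuracy / med))
            if plan is not None:
                for tr, c, r in zip(plan.trials, correct, rt):
                    trial_rows.append(
                        (subj, ti, tr.index, tr.category.value, tr.orientation.value,
                         int(tr.congruent), int(c), float(r))
                    )
    truth = pd.DataFrame(
        {
            "subject_id": [f"s{i + 1:03d}" for i in range(spec.n_subjects)],
            "b0i": [m.b0i for m in models],
            "b1": spec.base.b1,
            "b2": spec.base.b2,
            "b3": spec.base.b3,
            "sigma": spec.base.sigma,
            "alpha0": spec.base.alpha0,
            "alpha1": spec.base.alpha1,
            "alpha2": spec.base.alpha2,
        }
    )
    metrics = pd.DataFrame(
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
    if detail == "trials":
        from .session_engine import LOG_COLUMNS

        return pd.DataFrame(trial_rows, columns=LOG_COLUMNS), truth
    return metrics, truth
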