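"""Statistical pipeline of the three-arm craving trial.

Covers, on a long-format craving table (subject x group x timepoint, 0-100
visual-analogue scores):

- intention-to-treat completion by last-observation-carried-forward (LOCF);
- the mixed-design (split-plot) ANOVA group-by-time interaction with
  partial eta squared, plus a subject-level nonparametric bootstrap with
  bias-corrected-and-accelerated (BCa) confidence intervals and a
  group-label permutation p-value;
- bootstrapped pairwise contrasts with Cohen d and Bonferroni adjustment;
- a k-sample equality-of-proportions chi-square for relapse counts; and
- the retrospective random-intercept linear mixed model of the session
  performance index on ITR, ITR squared, t, t squared and the rolling ITR
  SD, with Wald-t confidence intervals and conditional R squared.

The interaction sum of squares is computed in the within-subject stratum by
model comparison (cell-mean fit vs time-mean fit of the subject-centered
scores), which reduces to the textbook split-plot decomposition for
balanced groups and handles unequal group sizes; because the interaction is
the highest-order term, this equals its Type III sum of squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GROUPS",
    "TIMEPOINTS",
    "AnovaResult",
    "MixedModelResult",
    "PairwiseResult",
    "locf_impute",
    "mixed_anova",
    "bootstrap_interaction",
    "pairwise_craving_tests",
    "relapse_prop_test",
    "fit_mixed_model",
]

GROUPS = ("control", "s_apbm", "a_apbm")
TIMEPOINTS = ("baseline", "post", "followup")


# ---------------------------------------------------------------------------
# table plumbing

def _check_table(df: pd.DataFrame) -> None:
    required = {"subject_id", "group", "timepoint", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"craving table missing columns: {sorted(missing)}")
    dup = df.duplicated(["subject_id", "timepoint"])
    if dup.any():
        raise ValueError("at most one row per subject x timepoint")


def _to_wide(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    """Wide score matrix (subjects x timepoints), group codes, subject index."""
    _check_table(df)
    wide = df.pivot(index="subject_id", columns="timepoint", values="score")
    order = [tp for tp in TIMEPOINTS if tp in wide.columns]
    wide = wide[order]
    if wide.isna().any().any():
        raise ValueError("table has missing scores; run locf_impute first")
    grp = df.drop_duplicates("subject_id").set_index("subject_id")["group"]
    grp = grp.loc[wide.index]
    groups_present = [g for g in GROUPS if g in set(grp)]
    codes = np.array([groups_present.index(g) for g in grp], dtype=int)
    return wide.to_numpy(dtype=float), codes, wide.index


def locf_impute(df: pd.DataFrame) -> pd.DataFrame:
    """Complete a craving table by carrying each subject's last score forward.

    Baseline must be present for every subject (it is the averaged double
    rating taken at enrollment).  The returned table has one row per subject
    and timepoint plus an ``imputed`` flag.
    """
    _check_table(df)
    wide = df.pivot(index="subject_id", columns="timepoint", values="score")
    for tp in TIMEPOINTS:
        if tp not in wide.columns:
            wide[tp] = np.nan
    wide = wide[list(TIMEPOINTS)]
    if wide["baseline"].isna().any():
        bad = wide.index[wide["baseline"].isna()][0]
        raise ValueError(f"baseline score missing for subject {bad!r}")
    filled = wide.ffill(axis=1)
    imputed = wide.isna()
    grp = df.drop_duplicates("subject_id").set_index("subject_id")["group"]
    out = (
        filled.reset_index()
        .melt(id_vars="subject_id", var_name="timepoint", value_name="score")
    )
    flags = imputed.reset_index().melt(
        id_vars="subject_id", var_name="timepoint", value_name="imputed"
    )
    out["imputed"] = flags["imputed"]
    out["group"] = out["subject_id"].map(grp)
    out["timepoint"] = pd.Categorical(out["timepoint"], TIMEPOINTS, ordered=True)
    return out.sort_values(["subject_id", "timepoint"]).reset_index(drop=True)[
        ["subject_id", "group", "timepoint", "score", "imputed"]
    ]


# ---------------------------------------------------------------------------
# split-plot ANOVA interaction

@dataclass
class AnovaResult:
    """Group-by-time interaction of the mixed-design ANOVA."""

    F: float
    df_num: int
    df_den: int
    partial_eta_sq: float
    ss_interaction: float
    ss_error: float
    p_parametric: float
    ci_F: tuple[float, float] | None = None
    ci_eta: tuple[float, float] | None = None
    p: float | None = None
    n_resamples: int = 0
    degenerate: bool = False


def _interaction_ss(Z: np.ndarray, codes: np.ndarray, G: int) -> tuple[float, float]:
    """(SS_interaction, SS_error) from subject-centered scores ``Z``."""
    col = Z.mean(axis=0)
    sse_red = float(((Z - col) ** 2).sum())
    sse_full = 0.0
    for g in range(G):
        Zg = Z[codes == g]
        sse_full += float(((Zg - Zg.mean(axis=0)) ** 2).sum())
    return sse_red - sse_full, sse_full


def _interaction_stats(Y: np.ndarray, codes: np.ndarray) -> tuple[float, float, int, int, float, float]:
    N, T = Y.shape
    G = int(codes.max()) + 1
    Z = Y - Y.mean(axis=1, keepdims=True)
    ss_int, ss_err = _interaction_ss(Z, codes, G)
    df_num = (G - 1) * (T - 1)
    df_den = (N - G) * (T - 1)
    if ss_err <= 1e-300:
        return math.nan, math.nan, df_num, df_den, ss_int, ss_err
    F = (ss_int / df_num) / (ss_err / df_den)
    eta = ss_int / (ss_int + ss_err)
    return F, eta, df_num, df_den, ss_int, ss_err


def mixed_anova(df: pd.DataFrame) -> AnovaResult:
    """Mixed-design ANOVA interaction: time within subjects, group between.

    Degrees of freedom are the sphericity-assumed (uncorrected) values
    df_num = (G-1)(T-1), df_den = (N-G)(T-1); partial eta squared is
    SS_interaction / (SS_interaction + SS_error).  A table in which every
    subject is flat across time has zero within-subject error and is
    returned flagged ``degenerate`` with an undefined F.
    """
    Y, codes, _ = _to_wide(df)
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 subjects")
    F, eta, dfn, dfd, ss_i, ss_e = _interaction_stats(Y, codes)
    degenerate = not math.isfinite(F)
    p_par = float(stats.f.sf(F, dfn, dfd)) if not degenerate else math.nan
    return AnovaResult(
        F=F,
        df_num=dfn,
        df_den=dfd,
        partial_eta_sq=eta,
        ss_interaction=ss_i,
        ss_error=ss_e,
        p_parametric=p_par,
        degenerate=degenerate,
    )


def _batched_interaction(
    Yb: np.ndarray, codes: np.ndarray, G: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (F, eta) over a batch of score matrices (B, N, T)."""
    B, N, T = Yb.shape
    Z = Yb - Yb.mean(axis=2, keepdims=True)
    col = Z.mean(axis=1, keepdims=True)
    sse_red = ((Z - col) ** 2).sum(axis=(1, 2))
    sse_full = np.zeros(B)
    for g in range(G):
        Zg = Z[:, codes == g, :]
        sse_full += ((Zg - Zg.mean(axis=1, keepdims=True)) ** 2).sum(axis=(1, 2))
    ss_int = sse_red - sse_full
    df_num = (G - 1) * (T - 1)
    df_den = (N - G) * (T - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_int / df_num) / (sse_full / df_den)
        eta = ss_int / (ss_int + sse_full)
    return F, eta


def permutation_interaction_p(
    Y: np.ndarray, codes: np.ndarray, B: int, rng: np.random.Generator
) -> float:
    """Permutation p-value for the interaction: group labels shuffled across subjects."""
    F_obs, *_ = _interaction_stats(Y, codes)
    N = Y.shape[0]
    G = int(codes.max()) + 1
    perm = np.argsort(rng.random((B, N)), axis=1)
    F_perm, _ = _batched_interaction(Y[perm], np.sort(codes), G)
    # permuting rows while keeping a sorted label vector == permuting labels
    return float((1 + np.sum(F_perm >= F_obs)) / (B + 1))


def _bca_interval(
    theta_hat: float,
    boots: np.ndarray,
    jacks: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Bias-corrected and accelerated interval from bootstrap + jackknife draws."""
    boots = boots[np.isfinite(boots)]
    jacks = jacks[np.isfinite(jacks)]
    if boots.size == 0 or jacks.size == 0:
        return (math.nan, math.nan)
    prop = np.clip(np.mean(boots < theta_hat), 1e-9, 1 - 1e-9)
    z0 = stats.norm.ppf(prop)
    jm = jacks.mean()
    num = ((jm - jacks) ** 3).sum()
    den = 6.0 * (((jm - jacks) ** 2).sum()) ** 1.5
    a = num / den if den > 0 else 0.0
    out = []
    for z_alpha in (stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)):
        adj = z0 + (z0 + z_alpha) / (1 - a * (z0 + z_alpha))
        out.append(float(np.quantile(boots, stats.norm.cdf(adj))))
    return tuple(out)  # type: ignore[return-value]


def bootstrap_interaction(
    df: pd.DataFrame,
    B: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> AnovaResult:
    """Bootstrap the interaction F and partial eta squared; BCa 95% CIs.

    Subjects are resampled with replacement *within group*, keeping each
    subject's time series intact so the within-subject correlation survives
    resampling.  The p-value comes from a group-label permutation null with
    the same number of resamples.
    """
    if B < 100:
        warnings.warn(f"B={B} resamples is too few for stable intervals")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    res = mixed_anova(df)
    if res.degenerate:
        return res
    Y, codes, _ = _to_wide(df)
    N = Y.shape[0]
    G = int(codes.max()) + 1

    # within-group subject bootstrap, whole time series as the unit
    idx_parts = []
    for g in range(G):
        rows = np.flatnonzero(codes == g)
        idx_parts.append(rows[rng.integers(0, rows.size, size=(B, rows.size))])
    idx = np.concatenate(idx_parts, axis=1)
    F_boot, eta_boot = _batched_interaction(Y[idx], np.sort(codes), G)

    # jackknife over subjects for the acceleration constant
    F_jack = np.empty(N)
    eta_jack = np.empty(N)
    keep = np.ones(N, dtype=bool)
    for i in range(N):
        keep[i] = False
        F_jack[i], eta_jack[i], *_ = _interaction_stats(Y[keep], codes[keep])
        keep[i] = True

    res.ci_F = _bca_interval(res.F, F_boot, F_jack)
    res.ci_eta = _bca_interval(res.partial_eta_sq, eta_boot, eta_jack)
    res.p = permutation_interaction_p(Y, codes, B, rng)
    res.n_resamples = B
    return res


# ---------------------------------------------------------------------------
# pairwise contrasts

@dataclass
class PairwiseResult:
    """One contrast: Cohen d with bootstrap p and BCa / percentile CIs."""

    family: str
    group: str
    contrast: str
    d: float
    p: float
    p_bonferroni: float
    ci_bca: tuple[float, float]
    ci_percentile: tuple[float, float]
    degenerate: bool = False


def _boot_p_from_t(t_obs: float, t_null: np.ndarray) -> float:
    t_null = t_null[np.isfinite(t_null)]
    return float((1 + np.sum(np.abs(t_null) >= abs(t_obs))) / (t_null.size + 1))


def _paired_contrast(diff: np.ndarray, B: int, rng: np.random.Generator):
    n = diff.size
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.all(diff == 0):  # truly null contrast, not just degenerate
            return 0.0, 1.0, (0.0, 0.0), (0.0, 0.0), True
        return math.nan, math.nan, (math.nan,) * 2, (math.nan,) * 2, True
    d_obs = diff.mean() / sd
    t_obs = d_obs * math.sqrt(n)
    centered = diff - diff.mean()
    idx = rng.integers(0, n, size=(B, n))
    null = centered[idx]
    m = null.mean(axis=1)
    s = null.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = m / s * math.sqrt(n)
    p = _boot_p_from_t(t_obs, t_null)
    raw = diff[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        d_boot = raw.mean(axis=1) / raw.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_jack = np.array(
            [np.delete(diff, i).mean() / np.delete(diff, i).std(ddof=1) for i in range(n)]
        )
    ci_bca = _bca_interval(d_obs, d_boot, d_jack)
    fin = d_boot[np.isfinite(d_boot)]
    ci_pct = (float(np.quantile(fin, 0.025)), float(np.quantile(fin, 0.975)))
    return d_obs, p, ci_bca, ci_pct, False


def _pooled_d(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        return math.nan
    return (x.mean() - y.mean()) / math.sqrt(sp2)


def _between_contrast(x: np.ndarray, y: np.ndarray, B: int, rng: np.random.Generator):
    d_obs = _pooled_d(x, y)
    if not math.isfinite(d_obs):
        return math.nan, math.nan, (math.nan,) * 2, (math.nan,) * 2, True
    nx, ny = x.size, y.size
    se = math.sqrt(x.var(ddof=1) / nx + y.var(ddof=1) / ny)
    t_obs = (x.mean() - y.mean()) / se if se > 0 else math.inf
    xc, yc = x - x.mean(), y - y.mean()
    xb = xc[rng.integers(0, nx, size=(B, nx))]
    yb = yc[rng.integers(0, ny, size=(B, ny))]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = (xb.mean(axis=1) - yb.mean(axis=1)) / np.sqrt(
            xb.var(axis=1, ddof=1) / nx + yb.var(axis=1, ddof=1) / ny
        )
    p = _boot_p_from_t(t_obs, t_null)
    xr = x[rng.integers(0, nx, size=(B, nx))]
    yr = y[rng.integers(0, ny, size=(B, ny))]
    sp2 = ((nx - 1) * xr.var(axis=1, ddof=1) + (ny - 1) * yr.var(axis=1, ddof=1)) / (
        nx + ny - 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        d_boot = (xr.mean(axis=1) - yr.mean(axis=1)) / np.sqrt(sp2)
    z = np.concatenate([x, y])
    labels = np.r_[np.zeros(nx, bool), np.ones(ny, bool)]
    d_jack = np.array(
        [
            _pooled_d(np.delete(z, i)[~np.delete(labels, i)], np.delete(z, i)[np.delete(labels, i)])
            for i in range(nx + ny)
        ]
    )
    ci_bca = _bca_interval(d_obs, d_boot, d_jack)
    fin = d_boot[np.isfinite(d_boot)]
    ci_pct = (float(np.quantile(fin, 0.025)), float(np.quantile(fin, 0.975)))
    return d_obs, p, ci_bca, ci_pct, False


def pairwise_craving_tests(
    df: pd.DataFrame,
    B: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """All pairwise contrasts of the craving analysis, as one table.

    Within-group family (one per group x later timepoint): paired Cohen d on
    baseline-minus-later difference scores, so a craving *reduction* is a
    positive d.  Between-group family (one per group pair x timepoint):
    pooled-SD Cohen d.  Bootstrap two-tailed p-values use the centered-data
    t-statistic null; Bonferroni adjusts within each family (6 within-group,
    9 between-group contrasts).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Y, codes, subjects = _to_wide(df)
    grp_names = [g for g in GROUPS if g in set(df["group"])]
    results: list[PairwiseResult] = []

    within: list[tuple[str, str, np.ndarray]] = []
    for gi, g in enumerate(grp_names):
        block = Y[codes == gi]
        for ti, tp in enumerate(TIMEPOINTS[1:], start=1):
            within.append((g, f"baseline_vs_{tp}", block[:, 0] - block[:, ti]))
    m_within = len(within)
    for g, name, diff in within:
        d, p, bca, pct, degen = _paired_contrast(diff, B, rng)
        results.append(
            PairwiseResult(
                "within", g, name, d, p,
                min(1.0, p * m_within) if math.isfinite(p) else math.nan,
                bca, pct, degen,
            )
        )

    between = []
    for ti, tp in enumerate(TIMEPOINTS):
        for a in range(len(grp_names)):
            for b in range(a + 1, len(grp_names)):
                between.append((f"{grp_names[a]}_vs_{grp_names[b]}", tp, a, b, ti))
    m_between = len(between)
    for name, tp, a, b, ti in between:
        x, y = Y[codes == a, ti], Y[codes == b, ti]
        d, p, bca, pct, degen = _between_contrast(x, y, B, rng)
        results.append(
            PairwiseResult(
                "between", name, tp, d, p,
                min(1.0, p * m_between) if math.isfinite(p) else math.nan,
                bca, pct, degen,
            )
        )
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# relapse proportions

def relapse_prop_test(relapses, ns) -> tuple[float, int, float]:
    """Pearson chi-square test of equal relapse proportions across k arms.

    No continuity correction (matching the k>2 convention).  Under the
    intention-to-treat reading, pass ``observed + missing`` as ``relapses``.
    Returns (chi2, df, p).
    """
    x = np.asarray(relapses, dtype=int)
    n = np.asarray(ns, dtype=int)
    if x.size != n.size or x.size < 2:
        raise ValueError("need matching count vectors of length >= 2")
    if np.any(n <= 0):
        raise ValueError("all group sizes must be positive")
    if np.any(x < 0) or np.any(x > n):
        raise ValueError("relapse counts must lie in [0, n]")
    table = np.column_stack([x, n - x])
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


# ---------------------------------------------------------------------------
# retrospective mixed model

@dataclass
class MixedModelResult:
    """Random-intercept mixed model of performance on the difficulty features."""

    params: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    conditional_r2: float
    random_intercept_var: float
    resid_var: float
    converged: bool
    singular: bool
    method: str = "mixedlm"


MIXED_TERMS = ("itr", "itr_sq", "t", "t_sq", "itr_sd_k")


def _cluster_sandwich(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    beta: np.ndarray,
    tau2: float,
    s2: float,
) -> tuple[np.ndarray, int]:
    """CR1 cluster-robust covariance of the fixed effects, clusters = subjects.

    Uses the fitted random-intercept structure V_i = tau2 * J + s2 * I per
    subject (inverted in closed form) for the bread; the meat is the outer
    product of per-subject score contributions, scaled by G/(G-1).
    """
    k = X.shape[1]
    A = np.zeros((k, k))
    B = np.zeros((k, k))
    labels = np.unique(groups)
    for s in labels:
        m = groups == s
        Xi, ri = X[m], y[m] - X[m] @ beta
        ni = int(m.sum())
        Vinv = (np.eye(ni) - (tau2 / (s2 + ni * tau2)) * np.ones((ni, ni))) / s2
        XtV = Xi.T @ Vinv
        A += XtV @ Xi
        u = XtV @ ri
        B += np.outer(u, u)
    G = labels.size
    Ainv = np.linalg.inv(A)
    return Ainv @ B @ Ainv * G / (G - 1), G


def fit_mixed_model(
    session_metrics: pd.DataFrame,
    exclude_first: int = 3,
    standardize: bool = False,
    robust: bool = True,
) -> MixedModelResult:
    """Fit performance ~ ITR + ITR² + t + t² + rolling-SD with subject intercepts.

    The first ``exclude_first`` sessions are dropped (their ITRs are the
    constant warm-up and the rolling SD is undefined there).  Confidence
    intervals use a Wald t approximation; by default the fixed-effect
    covariance is the cluster-robust (subject-level) sandwich with G-1
    degrees of freedom, which stays calibrated when the session residuals
    carry mild heteroscedasticity the random-intercept model does not
    describe (as trial-level response noise does).  ``robust=False`` gives
    the model-based covariance with residual degrees of freedom.
    Conditional R² is (var_fixed + var_random) / (var_fixed + var_random +
    var_residual).  A singular random-effects fit falls back to pooled OLS
    and is flagged.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = session_metrics.copy()
    df = df[df["session_index"] > exclude_first].copy()
    df = df.dropna(subset=["itr_sd_k"])
    counts = df.groupby("subject_id").size()
    if (counts < 3).any():
        raise ValueError("need at least 3 usable sessions per subject")
    df["t"] = df["session_index"].astype(float)
    df["t_sq"] = df["t"] ** 2
    if standardize and df["performance"].std() > 0:
        df["performance"] = (
            df["performance"] - df["performance"].mean()
        ) / df["performance"].std()
    formula = "performance ~ itr + itr_sq + t + t_sq + itr_sd_k"

    singular = False
    converged = True
    method = "mixedlm"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, df, groups=df["subject_id"])
            fit = model.fit(reml=True)
            converged = bool(fit.converged)
            re_var = float(fit.cov_re.iloc[0, 0])
            resid_var = float(fit.scale)
            params = fit.fe_params
            bse = fit.bse_fe
            if not converged or not np.all(np.isfinite(bse)):
                raise np.linalg.LinAlgError("mixed fit did not converge")
        except Exception:
            singular = True
            method = "ols"
            ols = smf.ols(formula, df).fit()
            re_var, resid_var = 0.0, float(ols.mse_resid)
            params, bse = ols.params, ols.bse
            converged = True
        if method == "mixedlm" and re_var <= max(1e-10, 1e-6 * resid_var):
            singular = True

    n_obs = len(df)
    k_fe = len(params)
    dof = max(n_obs - k_fe, 1)
    if robust and resid_var > 1e-12 * max(1.0, float(np.var(df["performance"]))):
        X = np.column_stack(
            [np.ones(n_obs)] + [df[c].to_numpy() for c in MIXED_TERMS]
        )
        order = ["Intercept"] + list(MIXED_TERMS)
        beta = params[order].to_numpy()
        cov, G = _cluster_sandwich(
            X,
            df["performance"].to_numpy(),
            df["subject_id"].to_numpy(),
            beta,
            re_var,
            resid_var,
        )
        diag = np.diag(cov)
        if np.all(np.isfinite(diag)) and np.all(diag > 0):
            bse = pd.Series(np.sqrt(diag), index=order)[params.index]
            dof = max(G - 1, 1)
    tcrit = stats.t.ppf(0.975, dof)
    conf = pd.DataFrame(
        {"lower": params - tcrit * bse, "upper": params + tcrit * bse}
    )
    tvals = params / bse
    pvals = pd.Series(2 * stats.t.sf(np.abs(tvals), dof), index=params.index)

    X = df[list(MIXED_TERMS)].to_numpy()
    fixed_pred = params["Intercept"] + X @ params[list(MIXED_TERMS)].to_numpy()
    var_f = float(np.var(fixed_pred))
    denom = var_f + re_var + resid_var
    cond_r2 = (var_f + re_var) / denom if denom > 0 else math.nan
    return MixedModelResult(
        params=params,
        conf_int=conf,
        pvalues=pvals,
        conditional_r2=cond_r2,
        random_intercept_var=re_var,
        resid_var=resid_var,
        converged=converged,
        singular=singular,
        method=method,
    )
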