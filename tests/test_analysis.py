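import itertools
import math

import numpy as np
import pandas as pd
import pytest

from apbm.trial_analysis import (
    GROUPS,
    TIMEPOINTS,
    _bca_interval,
    _paired_contrast,
    bootstrap_interaction,
    fit_mixed_model,
    locf_impute,
    mixed_anova,
    pairwise_craving_tests,
    relapse_prop_test,
)
from apbm.virtual_participant import CohortSpec, random_schedule, simulate_cohort

from conftest import craving_frame


# ---------------------------------------------------------------------------
# LOCF

def test_locf_carries_last_observation_forward():
    df = craving_frame({"control": [[10, 5, math.nan], [7, math.nan, math.nan]],
                        "s_apbm": [[3, 2, 1]]})
    out = locf_impute(df)
    wide = out.pivot(index="subject_id", columns="timepoint", values="score")
    assert list(wide.loc["p001"]) == [10, 5, 5]
    assert list(wide.loc["p002"]) == [7, 7, 7]  # cascade from baseline
    assert list(wide.loc["p003"]) == [3, 2, 1]  # complete rows untouched


def test_locf_is_idempotent_and_flags_imputations():
    df = craving_frame({"control": [[10, 5, math.nan], [4, 4, 4]]})
    once = locf_impute(df)
    twice = locf_impute(once[["subject_id", "group", "timepoint", "score"]])
    assert once["score"].tolist() == twice["score"].tolist()
    assert once["imputed"].sum() == 1
    assert twice["imputed"].sum() == 0


def test_locf_requires_baseline():
    df = craving_frame({"control": [[math.nan, 5, 6], [4, 4, 4]]})
    with pytest.raises(ValueError, match="baseline"):
        locf_impute(df)


# ---------------------------------------------------------------------------
# mixed-design ANOVA

def _oracle_split_plot(Y, codes):
    """Textbook sums-of-squares decomposition (balanced groups)."""
    N, T = Y.shape
    G = int(codes.max()) + 1
    grand = Y.mean()
    m_t = Y.mean(axis=0)
    subj = Y.mean(axis=1)
    sizes = np.bincount(codes)
    m_g = np.array([Y[codes == g].mean() for g in range(G)])
    m_gt = np.array([Y[codes == g].mean(axis=0) for g in range(G)])
    ss_total = ((Y - grand) ** 2).sum()
    ss_between_subj = T * ((subj - grand) ** 2).sum()
    ss_time = N * ((m_t - grand) ** 2).sum()
    ss_int = sum(
        sizes[g] * ((m_gt[g] - m_g[g] - m_t + grand) ** 2).sum() for g in range(G)
    )
    ss_err = ss_total - ss_between_subj - ss_time - ss_int
    dfn, dfd = (G - 1) * (T - 1), (N - G) * (T - 1)
    F = (ss_int / dfn) / (ss_err / dfd)
    return F, ss_int, ss_time, ss_err, ss_total, ss_between_subj


def _random_balanced_table(rng, per_group=4):
    blocks = {}
    for g in GROUPS:
        base = rng.gamma(2.0, 6.0, size=per_group)
        blocks[g] = np.clip(base[:, None] + rng.normal(0, 3.0, (per_group, 3)), 0, 100)
    return craving_frame(blocks)


def test_interaction_f_matches_brute_force_decomposition(rng):
    df = _random_balanced_table(rng)  # 12-subject fixture
    res = mixed_anova(df)
    Y = df.pivot(index="subject_id", columns="timepoint", values="score")[
        list(TIMEPOINTS)
    ].to_numpy()
    codes = np.repeat([0, 1, 2], 4)
    F_oracle, ss_int, *_ = _oracle_split_plot(Y, codes)
    assert res.F == pytest.approx(F_oracle, abs=1e-10)
    assert res.ss_interaction == pytest.approx(ss_int, abs=1e-8)


def test_interaction_f_matches_pingouin(rng):
    pingouin = pytest.importorskip("pingouin")
    df = _random_balanced_table(rng, per_group=6)
    res = mixed_anova(df)
    pg = pingouin.mixed_anova(
        data=df, dv="score", within="timepoint", subject="subject_id", between="group"
    )
    row = pg[pg["Source"] == "Interaction"].iloc[0]
    assert res.F == pytest.approx(row["F"], rel=1e-9)
    assert res.df_num == row["DF1"] and res.df_den == row["DF2"]


def test_total_ss_is_conserved(rng):
    df = _random_balanced_table(rng, per_group=5)
    Y = df.pivot(index="subject_id", columns="timepoint", values="score")[
        list(TIMEPOINTS)
    ].to_numpy()
    codes = np.repeat([0, 1, 2], 5)
    _, ss_int, ss_time, ss_err, ss_total, ss_bs = _oracle_split_plot(Y, codes)
    assert ss_bs + ss_time + ss_int + ss_err == pytest.approx(ss_total, abs=1e-8)


@pytest.mark.parametrize("sizes", [(40, 48, 48), (10, 10, 10), (5, 7, 9)])
def test_df_bookkeeping_formula(rng, sizes):
    blocks = {
        g: rng.normal(10, 3, size=(n, 3)) for g, n in zip(GROUPS, sizes)
    }
    res = mixed_anova(craving_frame(blocks))
    N, G, T = sum(sizes), 3, 3
    assert (res.df_num, res.df_den) == ((G - 1) * (T - 1), (N - G) * (T - 1))


def test_flat_subjects_are_degenerate():
    df = craving_frame({g: np.tile([[5.0, 5.0, 5.0]], (3, 1)) * (i + 1)
                        for i, g in enumerate(GROUPS)})
    res = mixed_anova(df)
    assert res.degenerate
    assert math.isnan(res.F)


def test_group_with_single_subject_rejected():
    df = craving_frame({"control": [[1, 2, 3]], "s_apbm": [[1, 2, 3], [2, 3, 4]],
                        "a_apbm": [[1, 2, 3], [2, 3, 4]]})
    with pytest.raises(ValueError, match="2 subjects"):
        mixed_anova(df)


# ---------------------------------------------------------------------------
# bootstrap machinery

def test_bootstrap_is_seed_deterministic(balanced_craving):
    a = bootstrap_interaction(balanced_craving, B=300, seed=5)
    b = bootstrap_interaction(balanced_craving, B=300, seed=5)
    assert a.ci_F == b.ci_F and a.ci_eta == b.ci_eta and a.p == b.p


def test_bca_reduces_to_percentile_when_unbiased_and_symmetric(rng):
    x = rng.normal(0, 1, 5000)
    boots = np.concatenate([1 + x, 1 - x])  # symmetric about the estimate
    jacks = np.concatenate([x, -x])  # zero skew -> acceleration 0
    lo, hi = _bca_interval(1.0, boots, jacks)
    assert lo == pytest.approx(np.quantile(boots, 0.025), abs=1e-9)
    assert hi == pytest.approx(np.quantile(boots, 0.975), abs=1e-9)


def test_bootstrap_ci_brackets_the_observed_statistic(balanced_craving):
    res = bootstrap_interaction(balanced_craving, B=500, seed=9)
    assert res.ci_F[0] <= res.F <= res.ci_F[1]
    assert res.ci_eta[0] <= res.partial_eta_sq <= res.ci_eta[1]


# ---------------------------------------------------------------------------
# pairwise contrasts

def test_identical_timepoints_give_null_cohen_d():
    scores = np.array([[10.0, 10.0, 3.0], [6.0, 6.0, 2.0], [8.0, 8.0, 1.0],
                       [5.0, 5.0, 0.0]])
    df = craving_frame({g: scores for g in GROUPS})
    out = pairwise_craving_tests(df, B=200, seed=0)
    row = out[(out.family == "within") & (out.contrast == "baseline_vs_post")].iloc[0]
    assert row.d == 0.0 and row.degenerate


def test_constant_nonzero_diffs_flagged_degenerate():
    scores = np.array([[10.0, 9.0, 3.0], [6.0, 5.0, 2.0], [8.0, 7.0, 1.0]])
    df = craving_frame({g: scores for g in GROUPS})
    out = pairwise_craving_tests(df, B=200, seed=0)
    row = out[(out.family == "within") & (out.contrast == "baseline_vs_post")].iloc[0]
    assert row.degenerate and math.isnan(row.d)


def test_paired_d_estimator_is_nearly_unbiased(rng):
    true_delta, n, reps = 0.35, 48, 200
    est = []
    for _ in range(reps):
        diff = rng.normal(true_delta, 1.0, size=n)
        d, *_ = _paired_contrast(diff, B=50, rng=rng)
        est.append(d)
    assert abs(np.mean(est) - true_delta) < 0.05


def test_craving_reduction_reports_positive_d(rng):
    base = rng.gamma(3, 4, size=40)
    post = base - 3.0 + rng.normal(0, 1.0, size=40)  # genuine reduction
    scores = np.column_stack([base, post, post])
    df = craving_frame({g: scores for g in GROUPS})
    out = pairwise_craving_tests(df, B=500, seed=1)
    within = out[out.family == "within"]
    assert (within.d > 0).all()
    assert (within.p < 0.05).all()


def test_bonferroni_never_decreases_p(balanced_craving):
    out = pairwise_craving_tests(balanced_craving, B=200, seed=2)
    ok = out.dropna(subset=["p"])
    assert (ok.p_bonferroni >= ok.p - 1e-12).all()
    assert (ok.p_bonferroni <= 1.0).all()


# ---------------------------------------------------------------------------
# relapse proportions

def test_itt_reconstruction_reproduces_the_printed_p_value():
    chi2, dof, p = relapse_prop_test([2, 0, 3], [40, 48, 48])
    assert dof == 2
    assert round(p, 2) == 0.23


def test_equal_proportions_are_perfectly_homogeneous():
    chi2, dof, p = relapse_prop_test([1, 1, 1], [10, 10, 10])
    assert chi2 == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_two_by_two_closed_form():
    chi2, dof, p = relapse_prop_test([5, 0], [10, 10])
    assert chi2 == pytest.approx(20 * (5 * 10) ** 2 / (10 * 10 * 5 * 15))
    assert dof == 1


def _pearson_oracle(x, n):
    table = np.array([x, [ni - xi for xi, ni in zip(x, n)]], dtype=float).T
    col = table.sum(axis=0)
    row = table.sum(axis=1)
    total = table.sum()
    if (col == 0).any():
        return None
    expected = np.outer(row, col) / total
    return float(((table - expected) ** 2 / expected).sum())


def test_matches_generic_pearson_oracle_on_small_tables():
    ns = (3, 4, 5)
    for x in itertools.product(range(4), range(4), range(4)):
        if any(xi > ni for xi, ni in zip(x, ns)):
            continue
        oracle = _pearson_oracle(x, ns)
        if oracle is None:
            continue
        chi2, dof, _ = relapse_prop_test(list(x), list(ns))
        assert chi2 == pytest.approx(oracle, abs=1e-10)
        assert dof == 2


@pytest.mark.parametrize("x, n", [([1], [10]), ([2, 3], [10, 0]), ([5, 3], [4, 10])])
def test_invalid_relapse_inputs_rejected(x, n):
    with pytest.raises(ValueError):
        relapse_prop_test(x, n)


# ---------------------------------------------------------------------------
# retrospective mixed model

def test_zero_tau_fixed_effects_match_pooled_ols():
    import statsmodels.formula.api as smf

    spec = CohortSpec(n_subjects=12, tau=0.0, seed=4)
    met, _ = simulate_cohort(spec, lambda r: random_schedule(12, r))
    res = fit_mixed_model(met)
    assert res.random_intercept_var < 1e-4
    assert res.singular
    df = met[met.session_index > 3].dropna(subset=["itr_sd_k"]).copy()
    df["t"] = df["session_index"].astype(float)
    df["t_sq"] = df["t"] ** 2
    ols = smf.ols("performance ~ itr + itr_sq + t + t_sq + itr_sd_k", df).fit()
    for name in res.params.index:
        assert res.params[name] == pytest.approx(ols.params[name], abs=1e-3)


def test_noiseless_metrics_give_conditional_r2_of_one():
    rows = []
    for s in range(6):
        itrs = np.linspace(0.5, 1.0, 12)
        for t, itr in enumerate(itrs, start=1):
            sd = float(np.std(itrs[max(0, t - 3):t], ddof=1)) if t >= 3 else math.nan
            perf = 0.1 + 0.02 * itr - 0.03 * itr**2 + 0.001 * t
            rows.append((f"s{s}", t, itr, itr**2, sd, 0.9, 7.0, perf))
    met = pd.DataFrame(rows, columns=["subject_id", "session_index", "itr", "itr_sq",
                                      "itr_sd_k", "accuracy", "median_log_rt",
                                      "performance"])
    res = fit_mixed_model(met)
    assert res.conditional_r2 > 0.999


def test_true_slopes_recovered_within_cis_on_one_cohort():
    spec = CohortSpec(n_subjects=50, seed=11)
    met, _ = simulate_cohort(spec, lambda r: random_schedule(28, r))
    res = fit_mixed_model(met)
    b = spec.base
    truth = {"itr_sq": b.b1 * b.alpha1, "t": b.b2, "itr_sd_k": b.b1 * b.alpha2}
    for name, val in truth.items():
        lo, hi = res.conf_int.loc[name]
        assert lo <= val <= hi
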