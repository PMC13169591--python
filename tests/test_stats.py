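"""Statistics engine: normative Z-scoring, impairment rule, comparisons,
FDR, Spearman, adjusted models, ROC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from alpscog import (
    adjusted_linear_model,
    classify_impairment,
    compare_groups,
    fdr_bh,
    fit_normative,
    roc_auc,
    spearman_matrix,
    summary_ttest,
    z_transform,
)
from alpscog.stats import cohens_d, effect_size_r, mannwhitney_z


def _hc_frame(n, rng, score_fn, age=None):
    age = rng.uniform(20, 65, n) if age is None else age
    sex = (rng.random(n) < 0.4).astype(int)
    edu = rng.uniform(6, 18, n)
    return pd.DataFrame(
        {"age": age, "sex": sex, "education": edu, "score": score_fn(age, sex, edu)}
    )


# -- normative models -------------------------------------------------------

def test_noiseless_normative_recovery_flags_degenerate(rng):
    df = _hc_frame(50, rng, lambda a, s, e: 50 - 0.2 * a)
    model = fit_normative(df, "score")
    assert model.coef["age"] == pytest.approx(-0.2, abs=1e-9)
    assert model.intercept == pytest.approx(50.0, abs=1e-7)
    assert model.degenerate


def test_normative_monte_carlo_scale(rng):
    df = _hc_frame(500, rng, lambda a, s, e: 50 + rng.normal(0, 10, len(a)))
    model = fit_normative(df, "score")
    at_mean = model.predict(
        {"age": df.age.mean(), "sex": df.sex.mean(), "education": df.education.mean()}
    )
    assert at_mean == pytest.approx(50, rel=0.05)
    assert abs(model.coef["age"]) < 0.1
    assert model.residual_scale == pytest.approx(10, rel=0.05)


def test_normative_permutation_invariance(rng):
    df = _hc_frame(60, rng, lambda a, s, e: 40 + 0.5 * e + rng.normal(0, 3, len(a)))
    m1 = fit_normative(df, "score")
    m2 = fit_normative(df.sample(frac=1, random_state=1), "score")
    assert m1.coef == pytest.approx(m2.coef)
    assert m1.residual_scale == pytest.approx(m2.residual_scale)


def test_collinear_normative_design_rejected(rng):
    df = _hc_frame(30, rng, lambda a, s, e: 50 + rng.normal(0, 5, len(a)))
    df["education"] = 2 * df["age"]
    with pytest.raises(ValueError, match="collinear"):
        fit_normative(df, "score")


def test_too_few_hc_rows_rejected(rng):
    with pytest.raises(ValueError, match=">= 5"):
        fit_normative(_hc_frame(4, rng, lambda a, s, e: a), "score")


def test_z_transform_centering_and_arithmetic(rng):
    df = _hc_frame(100, rng, lambda a, s, e: 50 + 0.3 * e + rng.normal(0, 8, len(a)))
    model = fit_normative(df, "score")
    subj = {"age": 40.0, "sex": 1, "education": 12.0}
    subj["score"] = model.predict(subj)
    assert z_transform(model, subj) == pytest.approx(0.0, abs=1e-12)
    # covariate-free arithmetic: mean 50, scale 10, raw 35 -> Z = -1.5
    flat = pd.DataFrame({"x": np.zeros(10), "score": np.r_[np.full(5, 40.0), np.full(5, 60.0)]})
    m0 = fit_normative(flat, "score", covariates=())
    scale = np.sqrt(((flat.score - 50) ** 2).sum() / 9)
    assert z_transform(m0, {"score": 50 - 1.5 * scale}) == pytest.approx(-1.5, abs=1e-9)


def test_hc_sample_mean_z_is_zero(rng):
    """OLS residual identity: Z over the fitting sample averages to 0."""
    df = _hc_frame(80, rng, lambda a, s, e: 45 - 0.1 * a + rng.normal(0, 6, len(a)))
    model = fit_normative(df, "score")
    zs = [z_transform(model, row) for _, row in df.iterrows()]
    assert np.mean(zs) == pytest.approx(0.0, abs=1e-9)


# -- impairment rule --------------------------------------------------------

@pytest.mark.parametrize(
    "zs, expected",
    [
        ((-1.6, -1.5, 0.0), "impaired"),  # boundary counts as impaired domain
        ((-1.4, -1.4, -1.4), "preserved"),
        ((-3.0, 0.0, 0.0), "preserved"),
        ((-1.5, -1.5, -1.5), "impaired"),
        ((0.0, 0.0, 0.0), "preserved"),
        ((-2.0, -2.0, 1.0), "impaired"),
        ((1.0, -5.0, -1.51), "impaired"),
        ((-1.49, -1.49, 2.0), "preserved"),
    ],
)
def test_impairment_truth_table(zs, expected):
    assert classify_impairment(*zs) == expected


@settings(max_examples=100, deadline=None, derandomize=True)
@given(zs=st.tuples(*[st.floats(-4, 4) for _ in range(3)]), drop=st.floats(0, 3), idx=st.integers(0, 2))
def test_impairment_monotone_in_each_domain(zs, drop, idx):
    """Decreasing any Z never flips impaired -> preserved."""
    worse = list(zs)
    worse[idx] -= drop
    if classify_impairment(*zs) == "impaired":
        assert classify_impairment(*worse) == "impaired"


def test_missing_z_rejected():
    with pytest.raises(ValueError, match="missing"):
        classify_impairment(-1.6, np.nan, 0.0)


# -- group comparisons ------------------------------------------------------

def _two_group(rng, n1=40, n2=40, loc2=0.0, skew=False):
    if skew:
        a, b = rng.exponential(1, n1), rng.exponential(1, n2) + loc2
    else:
        a, b = rng.normal(0, 1, n1), rng.normal(loc2, 1, n2)
    return pd.DataFrame({"group": ["A"] * n1 + ["B"] * n2, "v": np.r_[a, b]})


def test_normal_data_gated_to_t_test(rng):
    res = compare_groups(_two_group(rng, loc2=1.0), "v")
    assert res.test == "t"
    assert res.effect_size_type == "cohens_d"
    assert "mean" in res.descriptives["A"]


def test_skewed_data_gated_to_mann_whitney(rng):
    res = compare_groups(_two_group(rng, n1=80, n2=80, loc2=1.0, skew=True), "v")
    assert res.test == "mann-whitney"
    assert res.effect_size_type == "r"
    assert "median" in res.descriptives["A"]


def test_categorical_gated_to_chi_square(rng):
    df = pd.DataFrame({"group": ["A"] * 40 + ["B"] * 40, "v": rng.integers(0, 2, 80)})
    res = compare_groups(df, "v", categorical=True)
    assert res.test == "chi-square"


def test_identical_groups_degenerate():
    df = pd.DataFrame({"group": ["A"] * 5 + ["B"] * 5, "v": 3.0})
    res = compare_groups(df, "v")
    assert (res.statistic, res.p, res.effect_size) == (0.0, 1.0, 0.0)


def test_comparison_invariant_to_row_order(rng):
    df = _two_group(rng, loc2=0.7)
    r1 = compare_groups(df, "v")
    r2 = compare_groups(df.sample(frac=1, random_state=3), "v")
    assert r1.statistic == pytest.approx(r2.statistic)
    assert r1.p == pytest.approx(r2.p)


def test_effect_size_r_reproduces_published_convention():
    # Z = -5.088 on a total study of 86 -> r = 0.549
    assert effect_size_r(-5.088, 86) == pytest.approx(0.549, abs=1e-3)


def test_mannwhitney_z_matches_scipy_asymptotic(rng):
    x, y = rng.normal(0, 1, 30), rng.normal(0.8, 1, 25)
    u1, z, p = mannwhitney_z(x, y)
    u_ref, p_ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=False)
    assert u1 == pytest.approx(u_ref)
    assert p == pytest.approx(p_ref, rel=1e-9)


def test_summary_ttest_from_printed_group_summaries():
    """Welch t and pooled-SD Cohen's d reconstructed from mean/SEM/n
    summaries of an intracranial-volume comparison."""
    res = summary_ttest(1384.66, 23.89, 45, 1443.27, 22.81, 41)
    assert res.t == pytest.approx(-1.765, abs=0.02)
    assert res.d == pytest.approx(0.381, abs=5e-4)


def test_summary_ttest_equal_means_zero():
    res = summary_ttest(10.0, 1.0, 20, 10.0, 1.5, 25)
    assert res.t == 0.0 and res.d == 0.0


def test_summary_ttest_agrees_with_full_data_welch(rng):
    """Two-point samples moment-matched to (mean, SEM, n) give the same
    Welch t from raw data as from the summaries."""
    def sample(mean, sd, n):
        a = sd * np.sqrt((n - 1) / n)
        return mean + a * np.r_[np.ones(n // 2), -np.ones(n // 2)]

    m1, s1, n1, m2, s2, n2 = 12.0, 3.0, 40, 10.5, 2.0, 36
    x, y = sample(m1, s1, n1), sample(m2, s2, n2)
    t_raw, _ = sps.ttest_ind(x, y, equal_var=False)
    res = summary_ttest(m1, s1 / np.sqrt(n1), n1, m2, s2 / np.sqrt(n2), n2)
    assert res.t == pytest.approx(t_raw, abs=1e-9)


# -- FDR --------------------------------------------------------------------

def brute_force_bh(p):
    """Step-up definition evaluated literally: q(i) = min_{j>=i} m p(j)/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [m * p[order[j]] / (j + 1) for j in range(rank_pos, m)]
        q[idx] = min(1.0, min(candidates))
    return q


def test_fdr_worked_example():
    np.testing.assert_allclose(fdr_bh([0.005, 0.03, 0.5]), [0.015, 0.045, 0.5])


def test_fdr_single_p_and_empty():
    assert fdr_bh([0.2]) == pytest.approx([0.2])
    assert fdr_bh([]).size == 0


def test_fdr_matches_brute_force_on_random_vectors(rng):
    for _ in range(100):
        p = rng.uniform(0, 1, rng.integers(1, 40))
        np.testing.assert_allclose(fdr_bh(p), brute_force_bh(p), atol=1e-12)


def test_fdr_dominates_p_and_is_rank_monotone(rng):
    p = rng.uniform(0, 1, 25)
    q = fdr_bh(p)
    assert np.all(q >= p - 1e-15)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-15)


def test_fdr_rejects_invalid_p():
    with pytest.raises(ValueError):
        fdr_bh([0.5, 1.2])


# -- Spearman ---------------------------------------------------------------

def test_spearman_monotone_and_antitone(rng):
    x = rng.uniform(0, 1, 30)
    df = pd.DataFrame({"x": x, "up": np.exp(x), "down": -x})
    rho, p = spearman_matrix(df, ["x"], ["up", "down"])
    assert rho.loc["x", "up"] == pytest.approx(1.0)
    assert rho.loc["x", "down"] == pytest.approx(-1.0)


def test_spearman_constant_column_flagged_undefined(rng):
    df = pd.DataFrame({"x": rng.uniform(0, 1, 20), "c": 1.0})
    rho, p = spearman_matrix(df, ["x"], ["c"])
    assert np.isnan(rho.loc["x", "c"])


def test_spearman_null_mean_near_zero(rng):
    rhos = []
    for _ in range(100):
        df = pd.DataFrame({"x": rng.normal(size=200), "y": rng.normal(size=200)})
        rho, _ = spearman_matrix(df, ["x"], ["y"])
        rhos.append(rho.iloc[0, 0])
    assert abs(np.mean(rhos)) < 0.05


# -- adjusted linear models -------------------------------------------------

def test_noiseless_adjusted_model_recovery(rng):
    n = 60
    df = pd.DataFrame(
        {
            "age": rng.uniform(20, 60, n),
            "sex": (rng.random(n) < 0.5).astype(int),
            "education": rng.uniform(6, 18, n),
            "alps": rng.normal(1.5, 0.2, n),
        }
    )
    df["z"] = 2 + 3 * df["alps"]
    res = adjusted_linear_model(df, "z", ["alps"])
    assert res.terms.loc["alps", "B"] == pytest.approx(3.0, abs=1e-9)
    assert res.terms.loc["alps", "vif"] == pytest.approx(1.0, abs=0.2)
    assert res.terms.loc["alps", "ci_low"] <= 3.0 <= res.terms.loc["alps", "ci_high"]


def test_duplicate_and_aliased_predictors_rejected(rng):
    n = 40
    df = pd.DataFrame(
        {
            "age": rng.uniform(20, 60, n),
            "sex": (rng.random(n) < 0.5).astype(int),
            "education": rng.uniform(6, 18, n),
            "a": rng.normal(size=n),
        }
    )
    df["b"] = 2 * df["a"]
    df["z"] = rng.normal(size=n)
    with pytest.raises(ValueError, match="duplicated"):
        adjusted_linear_model(df, "z", ["a", "a"])
    with pytest.raises(ValueError, match="aliased"):
        adjusted_linear_model(df, "z", ["a", "b"])


# -- ROC --------------------------------------------------------------------

def test_roc_perfect_and_tied():
    assert roc_auc([0.9, 0.8, 0.7], [1, 1, 0]) == pytest.approx(1.0)
    assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == pytest.approx(0.5)


def test_roc_matches_pairwise_oracle_and_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    for n in (10, 57, 200):
        scores = rng.normal(size=n)
        scores[: n // 3] = np.round(scores[: n // 3], 1)  # induce ties
        labels = (rng.random(n) < 0.4).astype(int)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        pos, neg = scores[labels == 1], scores[labels == 0]
        pairs = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
        oracle = pairs / (len(pos) * len(neg))
        got = roc_auc(scores, labels)
        assert got == pytest.approx(oracle, abs=1e-12)
        assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_roc_orientation_flag(rng):
    scores, labels = [0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]
    auc, direction = roc_auc(scores, labels, orient=True)
    assert auc == pytest.approx(1.0) and direction == -1


def test_roc_single_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        roc_auc([1.0, 2.0], [1, 1])
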