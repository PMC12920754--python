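"""Group tests, correlations, ROC, and one-way ICC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from nodalcut import anova_tukey, icc_oneway, mann_whitney, pearson_fdr, roc_curve_auc
from nodalcut.stats import reader_matrix


def test_mann_whitney_exact_enumeration():
    res = mann_whitney([1, 2], [3, 4])
    assert res.method == "exact"
    assert res.pvalue == pytest.approx(2 / 6)


def test_mann_whitney_null_identity():
    res = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    assert res.pvalue >= 0.99


def test_mann_whitney_type_one_error_rate():
    rng = np.random.default_rng(8)
    rejections = 0
    n_rep = 1000
    for _ in range(n_rep):
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        rejections += mann_whitney(x, y).pvalue < 0.05
    assert 0.03 <= rejections / n_rep <= 0.07


def test_mann_whitney_empty_group():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


def test_anova_identical_groups():
    g = [1.0, 2.0, 3.0]
    res = anova_tukey({"a": g, "b": g, "c": g})
    assert res.f_statistic == pytest.approx(0.0)
    assert res.pvalue == pytest.approx(1.0)
    assert len(res.tukey) == 3


def test_anova_two_groups_equals_squared_t():
    rng = np.random.default_rng(12)
    x, y = rng.normal(size=15), rng.normal(loc=0.5, size=12)
    res = anova_tukey({"x": x, "y": y})
    t = ss.ttest_ind(x, y, equal_var=True)
    assert res.f_statistic == pytest.approx(t.statistic**2)
    assert res.pvalue == pytest.approx(t.pvalue)


def test_anova_null_type_one_rate():
    rng = np.random.default_rng(13)
    rejections = 0
    n_rep = 1000
    for _ in range(n_rep):
        groups = {k: rng.standard_normal(12) for k in "abc"}
        rejections += anova_tukey(groups).pvalue < 0.05
    assert 0.03 <= rejections / n_rep <= 0.07


def test_anova_degenerate_group():
    with pytest.raises(ValueError):
        anova_tukey({"a": [1.0], "b": [1.0, 2.0]})


def test_pearson_exact_linear_relations():
    x = np.arange(10, dtype=float)
    df = pd.DataFrame({"x": x, "y": 2 * x + 1, "z": -x})
    r, p, padj = pearson_fdr(df)
    assert r.loc["x", "y"] == pytest.approx(1.0)
    assert r.loc["x", "z"] == pytest.approx(-1.0)
    assert (padj.values[np.triu_indices(3, 1)] >= p.values[np.triu_indices(3, 1)] - 1e-15).all()


def test_pearson_matches_covariance_formula(rng):
    m = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
    r, _, _ = pearson_fdr(m)
    for i, a in enumerate("abc"):
        for b in "abc"[i + 1:]:
            x, y = m[a].to_numpy(), m[b].to_numpy()
            manual = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
            )
            assert r.loc[a, b] == pytest.approx(manual, abs=1e-12)


def test_pearson_pairwise_complete_and_constant_flagged():
    df = pd.DataFrame(
        {"a": [1.0, 2.0, 3.0, np.nan, 5.0], "b": [2.0, 4.0, 6.0, 8.0, 10.0], "c": [1.0] * 5}
    )
    r, p, _ = pearson_fdr(df)
    assert r.loc["a", "b"] == pytest.approx(1.0)  # computed on the 4 complete pairs
    assert np.isnan(r.loc["a", "c"]) and np.isnan(p.loc["b", "c"])


def test_roc_separable_and_null():
    assert roc_curve_auc([1, 2, 3, 8, 9], [0, 0, 0, 1, 1], "greater_equal").auc == 1.0
    rng = np.random.default_rng(4)
    v = rng.standard_normal(2000)
    t = rng.random(2000) < 0.5
    assert 0.46 <= roc_curve_auc(v, t, "greater_equal").auc <= 0.54


def test_roc_monotone_from_origin_to_one():
    rng = np.random.default_rng(44)
    curve = roc_curve_auc(rng.standard_normal(100), rng.random(100) < 0.3, "less_equal")
    assert curve.fpr[0] == curve.tpr[0] == 0.0
    assert curve.fpr[-1] == curve.tpr[-1] == 1.0
    assert (np.diff(curve.fpr) >= 0).all() and (np.diff(curve.tpr) >= 0).all()


def test_roc_invariant_under_monotone_transform(rng):
    v = np.abs(rng.standard_normal(200)) + 0.1
    t = rng.random(200) < 0.4
    a = roc_curve_auc(v, t, "greater_equal").auc
    b = roc_curve_auc(np.log(v), t, "greater_equal").auc
    assert a == pytest.approx(b)


def test_auc_equals_mann_whitney_statistic(rng):
    for _ in range(100):
        n1, n0 = int(rng.integers(5, 30)), int(rng.integers(5, 30))
        t = np.array([True] * n1 + [False] * n0)
        v = np.round(rng.standard_normal(n1 + n0), 1)  # ties on purpose
        auc = roc_curve_auc(v, t, "greater_equal").auc
        u = ss.mannwhitneyu(v[t], v[~t], alternative="two-sided").statistic
        assert auc == pytest.approx(u / (n1 * n0), abs=1e-12)


def test_icc_perfect_agreement():
    m = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0], [7.0, 7.0], [9.0, 9.0]])
    res = icc_oneway(m)
    assert res.icc == 1.0 and res.ci_low == 1.0


def test_icc_matches_hand_anova_decomposition():
    # 4 subjects x 2 raters, worked through the one-way mean squares directly
    m = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 7.0], [7.0, 9.0]])
    n, k = m.shape
    row_means = m.mean(axis=1)
    msb = k * np.sum((row_means - m.mean()) ** 2) / (n - 1)
    msw = np.sum((m - row_means[:, None]) ** 2) / (n * (k - 1))
    expected = (msb - msw) / (msb + (k - 1) * msw)
    res = icc_oneway(m, min_subjects=4)
    assert res.icc == pytest.approx(expected, abs=1e-12)
    assert res.ci_low <= res.icc <= res.ci_high


def test_icc_global_affine_invariance_and_negative_values(rng):
    m = rng.standard_normal((12, 3))
    a = icc_oneway(m)
    b = icc_oneway(3.5 * m + 100.0)
    assert a.icc == pytest.approx(b.icc, abs=1e-10)
    # pure-noise matrices can legitimately yield negative ICC
    noise = rng.standard_normal((40, 2)) * 5
    assert icc_oneway(noise).icc < 0.5


def test_icc_matches_pingouin_cross_check(rng):
    pingouin = pytest.importorskip("pingouin")
    m = rng.standard_normal((15, 3)) + rng.standard_normal((15, 1)) * 2
    res = icc_oneway(m)
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(15), 3),
            "rater": np.tile(np.arange(3), 15),
            "score": m.ravel(),
        }
    )
    pg = pingouin.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    row = pg.iloc[0]  # first row is the one-way single-rater ICC
    assert "1" in str(row["Type"])
    ci_col = "CI95%" if "CI95%" in pg.columns else "CI95"
    assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
    assert res.ci_low == pytest.approx(row[ci_col][0], abs=5e-3)
    assert res.ci_high == pytest.approx(row[ci_col][1], abs=5e-3)


def test_icc_complete_case_filtering_and_min_subjects():
    m = np.array([[1.0, 2.0], [np.nan, 4.0], [5.0, 6.0], [7.0, 8.0], [9.0, 8.0], [2.0, 2.5]])
    res = icc_oneway(m)
    assert res.n_subjects == 5
    with pytest.raises(ValueError, match="complete subjects"):
        icc_oneway(m[:5])  # only 4 complete rows


def test_reader_matrix_shapes(endo_cohort):
    _, tables, _ = endo_cohort
    mat = reader_matrix(tables.measurements, "FDG_PET", "suvmax")
    assert mat.shape[1] == 3  # two central + external
    mat_pt = reader_matrix(tables.measurements, "DWMRI", "adc_mean", region="primary_tumour")
    assert mat_pt.shape[1] == 2
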