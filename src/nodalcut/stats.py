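"""Group-difference, correlation, ROC, and interobserver-agreement statistics.

Cohorts are stratified by cancer type before any testing. Benign-vs-malignant
marker comparisons use the Mann-Whitney U test (exact enumeration for small
samples, tie-corrected normal approximation otherwise) with BH-FDR adjustment
across the family of tests in a run. Regional differences (left pelvic vs
right pelvic vs para-aortic) use one-way ANOVA with Tukey's post-hoc test;
when the omnibus test is non-significant the regions are pooled downstream.

Interobserver reliability uses the one-way random-effects intraclass
correlation ICC(1) = (MSB - MSW) / (MSB + (k-1) MSW) with an F-distribution
95% confidence interval. (A one-way model has no consistency/absolute-
agreement distinction; ICC(1) is what a "one-way, consistency" request
resolves to.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .compare import fdr_adjust

logger = logging.getLogger(__name__)


@dataclass
class GroupTestResult:
    statistic: float
    pvalue: float
    n_x: int
    n_y: int
    adjusted_pvalue: float = float("nan")
    method: str = ""


def mann_whitney(x, y, exact_max_n: int = 8) -> GroupTestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when the smaller group has <= ``exact_max_n``
    observations and the data are tie-free; tie-corrected normal
    approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if min(len(x), len(y)) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupTestResult(
        statistic=float(res.statistic), pvalue=float(res.pvalue),
        n_x=len(x), n_y=len(y), method=method,
    )


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    pvalue: float
    group_sizes: dict
    tukey: pd.DataFrame  # columns: group_a, group_b, adjusted_pvalue


def anova_tukey(groups: dict) -> AnovaTukeyResult:
    """One-way ANOVA across labelled groups plus Tukey HSD pairwise p-values."""
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if np.ptp(np.concatenate(arrays)) == 0:
        # all values identical everywhere: no variance to partition
        logger.warning("anova_tukey: zero total variance; returning F=0, p=1")
        tk = pd.DataFrame(
            [(labels[i], labels[j], 1.0) for i in range(len(labels)) for j in range(i + 1, len(labels))],
            columns=["group_a", "group_b", "adjusted_pvalue"],
        )
        return AnovaTukeyResult(0.0, 1.0, {g: len(a) for g, a in zip(labels, arrays)}, tk)
    f_res = stats.f_oneway(*arrays)
    t_res = stats.tukey_hsd(*arrays)
    rows = [
        (labels[i], labels[j], float(t_res.pvalue[i, j]))
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]
    return AnovaTukeyResult(
        f_statistic=float(f_res.statistic),
        pvalue=float(f_res.pvalue),
        group_sizes={g: len(a) for g, a in zip(labels, arrays)},
        tukey=pd.DataFrame(rows, columns=["group_a", "group_b", "adjusted_pvalue"]),
    )


def pearson_fdr(df: pd.DataFrame, min_n: int = 3):
    """Pairwise-complete Pearson correlations with BH adjustment over the
    upper triangle.

    Returns (r, raw p, adjusted p) DataFrames indexed by the input columns.
    Pairs with fewer than ``min_n`` complete observations or a constant vector
    are NaN (logged).
    """
    cols = list(df.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    np.fill_diagonal(r, 1.0)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            sub = df[[cols[i], cols[j]]].dropna()
            if len(sub) < min_n:
                logger.info("pearson_fdr: %s-%s has %d complete pairs (<%d)", cols[i], cols[j], len(sub), min_n)
                pairs.append(((i, j), np.nan))
                continue
            a, b = sub[cols[i]].to_numpy(), sub[cols[j]].to_numpy()
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                logger.warning("pearson_fdr: constant vector in pair %s-%s", cols[i], cols[j])
                pairs.append(((i, j), np.nan))
                continue
            res = stats.pearsonr(a, b)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
            pairs.append(((i, j), res.pvalue))
    adj_vals = fdr_adjust([pv for _, pv in pairs])
    p_adj = np.full((k, k), np.nan)
    for ((i, j), _), a_ in zip(pairs, adj_vals):
        p_adj[i, j] = p_adj[j, i] = a_
    mk = lambda m: pd.DataFrame(m, index=cols, columns=cols)
    return mk(r), mk(p), mk(p_adj)


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    direction: str


def roc_curve_auc(values, truths, direction: str = "greater_equal") -> ROCCurve:
    """Empirical ROC over all thresholds; trapezoidal AUC.

    ``less_equal`` markers (disease lowers the value) are handled by
    sign-flipping the scores.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(truths, dtype=bool)
    if not (t.any() and (~t).any()):
        raise ValueError("both classes must be present")
    scores = v if direction == "greater_equal" else -v
    fpr, tpr, thr = _sk_roc_curve(t.astype(int), scores)
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr,
                    auc=float(_trapezoid_auc(fpr, tpr)), direction=direction)


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    k_raters: int


def icc_oneway(ratings, confidence: float = 0.95, min_subjects: int = 5) -> ICCResult:
    """One-way random-effects ICC(1) with an F-distribution CI.

    ``ratings`` is subjects x raters; rows with any missing value are dropped
    (complete-case). ICC(1) = (MSB - MSW) / (MSB + (k-1) MSW); the CI follows
    Shrout & Fleiss via F = MSB/MSW:

        FL = F / F_{1-a/2}(n-1, n(k-1)),  FU = F * F_{1-a/2}(n(k-1), n-1),
        CI = ((FL-1)/(FL+k-1), (FU-1)/(FU+k-1)).

    The estimate can be negative when readers disagree more within subjects
    than subjects differ from each other.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("ratings must be a subjects x raters matrix with k >= 2")
    complete = ~np.isnan(m).any(axis=1)
    m = m[complete]
    n, k = m.shape
    if n < min_subjects:
        raise ValueError(f"need >= {min_subjects} complete subjects, got {n}")
    row_means = m.mean(axis=1)
    grand = m.mean()
    ssb = k * np.sum((row_means - grand) ** 2)
    ssw = np.sum((m - row_means[:, None]) ** 2)
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    if msw == 0 and msb == 0:
        raise ValueError("zero variance everywhere; ICC undefined")
    if msw == 0:
        return ICCResult(1.0, 1.0, 1.0, n, k)
    icc = (msb - msw) / (msb + (k - 1) * msw)
    f_obs = msb / msw
    a = 1 - confidence
    fl = f_obs / stats.f.ppf(1 - a / 2, n - 1, n * (k - 1))
    fu = f_obs * stats.f.ppf(1 - a / 2, n * (k - 1), n - 1)
    ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    return ICCResult(icc=float(icc), ci_low=float(ci[0]), ci_high=float(ci[1]),
                     n_subjects=n, k_raters=k)


def reader_matrix(measurements: pd.DataFrame, modality: str, measure: str,
                  readers=None, region=None) -> np.ndarray:
    """Pivot long measurement rows into a subjects x raters matrix for ICC.

    Subjects are (patient, region) keys (or the primary tumour rows when
    ``region="primary_tumour"``). ``readers`` defaults to every reader that
    measured this modality.
    """
    sub = measurements[(measurements["modality"] == modality) & (measurements["measure"] == measure)]
    if region is not None:
        sub = sub[sub["region"] == region]
    else:
        sub = sub[sub["region"] != "primary_tumour"]
    if readers is None:
        readers = sorted(sub["reader"].unique())
    wide = sub.pivot_table(index=["patient_id", "region"], columns="reader",
                           values="value", aggfunc="first")
    wide = wide.reindex(columns=readers)
    return wide.to_numpy(dtype=float)
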