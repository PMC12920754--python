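"""F_beta-optimal diagnostic cut-points with leave-one-out cross-validation.

The estimator searches the observed unique marker values as candidate
thresholds, classifies with an inclusive comparison (``value >= cutoff`` for
markers elevated in disease, ``value <= cutoff`` for markers depressed in
disease, e.g. ADC), and picks the candidate maximising the training-set
F_beta score. Out-of-sample performance is evaluated by leave-one-out
cross-validation: each region is classified by a cut-point fitted on all
other regions, and the median of the per-fold cut-offs is the reported
optimal cut-off.

Tie-breaking is deterministic: among F_beta-maximising candidates prefer
higher training specificity, then the largest cutoff for ``greater_equal``
(smallest for ``less_equal``) — conservative toward false positives.

The public surface follows the Model/Results convention::

    model = CutpointModel.from_dataframe(df, "fdg_suvmax")
    res = model.fit(beta=1.0)            # training-set optimum
    cv = model.fit_loocv(beta=1.0)       # held-out predictions + median OC
    print(cv.summary())
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import (
    ConfusionMatrix,
    DiagnosticPerformance,
    confusion_from_pairs,
    f_beta_score,
    performance_from_confusion,
    performance_with_ci,
)

logger = logging.getLogger(__name__)

GREATER_EQUAL = "greater_equal"
LESS_EQUAL = "less_equal"
DIRECTIONS = (GREATER_EQUAL, LESS_EQUAL)

DEFAULT_BETA_GRID = (0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class CutpointSpec:
    measure: str
    direction: str = GREATER_EQUAL
    beta: float = 1.0

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")


def candidate_thresholds(values) -> np.ndarray:
    """Sorted unique observed values; the candidate cut-off set."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to form candidate thresholds")
    if np.isnan(v).any():
        raise ValueError("candidate values must not contain NaN")
    return np.unique(v)


def classify_by_cutoff(values, cutoff: float, direction: str):
    """Inclusive threshold classification. Scalar in, scalar out."""
    v = np.asarray(values, dtype=float)
    if direction == GREATER_EQUAL:
        out = v >= cutoff
    elif direction == LESS_EQUAL:
        out = v <= cutoff
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return bool(out) if np.isscalar(values) or out.ndim == 0 else out


@dataclass
class CutpointResult:
    """An optimal cut-off with its training-set F_beta and confusion matrix."""

    cutoff: float
    f_beta: float
    confusion: ConfusionMatrix
    beta: float
    direction: str
    measure: str = ""
    degenerate: bool = False

    @property
    def performance(self) -> DiagnosticPerformance:
        return performance_from_confusion(self.confusion)


def _score_candidates(values: np.ndarray, truths: np.ndarray, direction: str, beta: float):
    """Vectorised training metrics for every candidate threshold.

    Returns (candidates, fbeta, sensitivity, specificity, confusion counts).
    """
    cands = candidate_thresholds(values)
    if direction == GREATER_EQUAL:
        preds = values[None, :] >= cands[:, None]
    else:
        preds = values[None, :] <= cands[:, None]
    truth = truths[None, :]
    tp = np.sum(preds & truth, axis=1)
    fp = np.sum(preds & ~truth, axis=1)
    fn = np.sum(~preds & truth, axis=1)
    tn = np.sum(~preds & ~truth, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        ppv = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan)
        denom = beta**2 * ppv + sens
        fbeta = np.where(denom > 0, (1 + beta**2) * ppv * sens / denom, np.nan)
    return cands, fbeta, sens, spec, (tp, fn, tn, fp)


def optimal_cutpoint(values, truths, spec: CutpointSpec) -> CutpointResult:
    """Exhaustive F_beta maximisation over observed candidate thresholds."""
    v = np.asarray(values, dtype=float)
    t = np.asarray(truths, dtype=bool)
    if v.shape != t.shape:
        raise ValueError("values and truths must align")
    degenerate = False
    if len(np.unique(v)) == 1:
        logger.warning("optimal_cutpoint: all values identical; degenerate candidate set")
        degenerate = True
    elif not (t.any() and (~t).any()):
        raise ValueError("both classes must be represented")
    cands, fbeta, sens, specif, (tp, fn, tn, fp) = _score_candidates(v, t, spec.direction, spec.beta)

    valid = ~np.isnan(fbeta)
    if not valid.any():
        # no candidate attains a defined F_beta (e.g. no positive predictions
        # anywhere); fall back to the full candidate list with F_beta = 0
        logger.warning("optimal_cutpoint: F_beta undefined for every candidate")
        fbeta = np.zeros_like(fbeta)
        valid = np.ones_like(valid)

    best_f = np.nanmax(np.where(valid, fbeta, -np.inf))
    tied = valid & np.isclose(fbeta, best_f, rtol=0, atol=1e-12)
    # tie-break 1: higher training specificity
    best_spec = np.nanmax(np.where(tied, specif, -np.inf))
    tied = tied & np.isclose(specif, best_spec, rtol=0, atol=1e-12)
    # tie-break 2: largest cutoff for greater_equal, smallest for less_equal
    idx = np.flatnonzero(tied)
    i = idx[-1] if spec.direction == GREATER_EQUAL else idx[0]

    return CutpointResult(
        cutoff=float(cands[i]),
        f_beta=float(fbeta[i]),
        confusion=ConfusionMatrix(tp=int(tp[i]), fn=int(fn[i]), tn=int(tn[i]), fp=int(fp[i])),
        beta=spec.beta,
        direction=spec.direction,
        measure=spec.measure,
        degenerate=degenerate,
    )


@dataclass
class CVPrediction:
    key: object
    prediction: bool | None
    fold_cutoff: float


def loocv_predict(values, truths, spec: CutpointSpec, keys=None):
    """Leave-one-out cross-validated predictions.

    For each region the optimal cut-off is fitted on all other regions and the
    held-out region is classified by it. Folds whose training data contain a
    single class yield an absent prediction with a warning. Returns
    ``(predictions, median_cutoff)`` where ``predictions`` is a list of
    :class:`CVPrediction`, one per record.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(truths, dtype=bool)
    n = len(v)
    if n < 3:
        raise ValueError("leave-one-out needs >= 3 records")
    if keys is None:
        keys = np.arange(n)
    preds: list[CVPrediction] = []
    cutoffs = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        vt, tt = v[mask], t[mask]
        if not (tt.any() and (~tt).any()):
            logger.warning("loocv_predict: fold %d has a single training class; absent prediction", i)
            preds.append(CVPrediction(key=keys[i], prediction=None, fold_cutoff=float("nan")))
            continue
        res = optimal_cutpoint(vt, tt, spec)
        cutoffs.append(res.cutoff)
        preds.append(
            CVPrediction(
                key=keys[i],
                prediction=bool(classify_by_cutoff(v[i], res.cutoff, spec.direction)),
                fold_cutoff=res.cutoff,
            )
        )
    median_cutoff = float(np.median(cutoffs)) if cutoffs else float("nan")
    return preds, median_cutoff


def beta_sweep(
    values,
    truths,
    spec: CutpointSpec,
    beta_grid=DEFAULT_BETA_GRID,
    bootstrap_B: int | None = None,
    seed=None,
) -> pd.DataFrame:
    """Out-of-sample performance of the LOOCV pipeline across a beta grid.

    One row per beta: median fold cut-off, confusion counts of the held-out
    predictions, and the five metrics (with bootstrap CIs if ``bootstrap_B``).
    """
    grid = np.asarray(beta_grid, dtype=float)
    if grid.size == 0 or not np.all(np.diff(grid) > 0):
        raise ValueError("beta grid must be non-empty and strictly increasing")
    rows = []
    for beta in grid:
        s = CutpointSpec(measure=spec.measure, direction=spec.direction, beta=float(beta))
        preds, med = loocv_predict(values, truths, s)
        mask = np.array([p.prediction is not None for p in preds])
        pred_vec = np.array([bool(p.prediction) for p in preds if p.prediction is not None])
        truth_vec = np.asarray(truths, dtype=bool)[mask]
        cm = confusion_from_pairs(pred_vec, truth_vec)
        if bootstrap_B:
            perf = performance_with_ci(pred_vec, truth_vec, B=bootstrap_B, seed=seed)
        else:
            perf = performance_from_confusion(cm)
        row = {
            "measure": spec.measure, "beta": float(beta), "median_cutoff": med,
            "n": cm.total, "tp": cm.tp, "fn": cm.fn, "tn": cm.tn, "fp": cm.fp,
            **perf.as_dict(),
        }
        for m, (lo, hi) in perf.ci.items():
            row[f"{m}_ci_low"], row[f"{m}_ci_high"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows)


class CutpointModel:
    """Threshold classifier for one quantitative measure.

    Parameters
    ----------
    values : array-like of float
        Fused marker values, one per nodal region (no NaN; filter upstream).
    truth : array-like of bool
        Histological truth per region.
    direction : str
        ``"greater_equal"`` (marker elevated in disease) or ``"less_equal"``.
    measure : str
        Name used in results and summaries.
    keys : array-like, optional
        Region identifiers carried through to CV predictions.
    """

    def __init__(self, values, truth, direction=GREATER_EQUAL, measure="marker", keys=None):
        v = np.asarray(values, dtype=float)
        t = np.asarray(truth, dtype=bool)
        if v.ndim != 1 or v.shape != t.shape:
            raise ValueError("values and truth must be equal-length 1-D")
        if np.isnan(v).any():
            raise ValueError("values contain NaN; drop incomplete regions first")
        self.values = v
        self.truth = t
        self.direction = direction
        self.measure = measure
        self.keys = np.asarray(keys) if keys is not None else np.arange(len(v))
        self.nobs = len(v)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, column: str, truth_col: str = "malignant",
                       direction: str | None = None):
        """Build from an analysis-region table, dropping rows with a missing
        marker value; direction defaults to the measure registry entry."""
        if direction is None:
            from .fusion import MEASURE_REGISTRY

            direction = MEASURE_REGISTRY.get(column, {}).get("direction", GREATER_EQUAL)
        sub = df[df[column].notna()]
        keys = list(zip(sub["patient_id"], sub["region"])) if {
            "patient_id", "region"
        } <= set(sub.columns) else None
        return cls(sub[column].to_numpy(dtype=float), sub[truth_col].to_numpy(dtype=bool),
                   direction=direction, measure=column, keys=keys)

    def fit(self, beta: float = 1.0) -> CutpointResult:
        """Training-set F_beta-optimal cut-off."""
        return optimal_cutpoint(
            self.values, self.truth,
            CutpointSpec(measure=self.measure, direction=self.direction, beta=beta),
        )

    def fit_loocv(self, beta: float = 1.0, bootstrap_B: int = 1000, seed=None) -> "CutpointCVResults":
        """Leave-one-out cross-validated fit with bootstrap CIs."""
        spec = CutpointSpec(measure=self.measure, direction=self.direction, beta=beta)
        preds, med = loocv_predict(self.values, self.truth, spec, keys=self.keys)
        mask = np.array([p.prediction is not None for p in preds])
        pred_vec = np.array([bool(p.prediction) for p in preds if p.prediction is not None])
        truth_vec = self.truth[mask]
        if bootstrap_B:
            perf = performance_with_ci(pred_vec, truth_vec, B=bootstrap_B, seed=seed)
        else:
            perf = performance_from_confusion(confusion_from_pairs(pred_vec, truth_vec))
        return CutpointCVResults(
            model=self, beta=beta, predictions=preds, median_cutoff=med,
            confusion=confusion_from_pairs(pred_vec, truth_vec), performance=perf,
        )

    def beta_sweep(self, beta_grid=DEFAULT_BETA_GRID, bootstrap_B=None, seed=None) -> pd.DataFrame:
        spec = CutpointSpec(measure=self.measure, direction=self.direction)
        return beta_sweep(self.values, self.truth, spec, beta_grid, bootstrap_B, seed)


@dataclass
class CutpointCVResults:
    """LOOCV results: held-out predictions, median optimal cut-off across
    folds (the reported OC), out-of-sample confusion and performance."""

    model: CutpointModel
    beta: float
    predictions: list[CVPrediction]
    median_cutoff: float
    confusion: ConfusionMatrix
    performance: DiagnosticPerformance
    _extra: dict = field(default_factory=dict)

    @property
    def prediction_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "key": [p.key for p in self.predictions],
                "prediction": [p.prediction for p in self.predictions],
                "fold_cutoff": [p.fold_cutoff for p in self.predictions],
            }
        )

    def summary(self) -> str:
        cm = self.confusion
        pct = self.performance.as_percent()
        lines = [
            f"Cut-point analysis: {self.model.measure}",
            f"  direction: {self.model.direction}, beta = {self.beta:g}",
            f"  n regions = {self.model.nobs}, diseased = {int(self.model.truth.sum())}",
            f"  median optimal cut-off (LOOCV): {self.median_cutoff:g}",
            f"  held-out confusion: TP={cm.tp} FN={cm.fn} TN={cm.tn} FP={cm.fp}",
        ]
        for m in ("sensitivity", "specificity", "ppv", "npv", "f1"):
            ci = self.performance.ci.get(m)
            ci_txt = f" (95% CI {100 * ci[0]:.1f}-{100 * ci[1]:.1f})" if ci else ""
            lines.append(f"  {m:>11}: {pct[m]:.1f}%{ci_txt}")
        return "\n".join(lines)
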