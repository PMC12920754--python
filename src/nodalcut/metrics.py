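"""Confusion matrices, diagnostic performance metrics, F_beta, and
percentile-bootstrap confidence intervals.

The F_beta score is the beta-weighted harmonic mean of sensitivity and
positive predictive value,

    F_beta = (1 + beta^2) * PPV * sens / (beta^2 * PPV + sens),

so beta = 1 balances the two (the F1 score), beta > 1 favours sensitivity and
beta < 1 favours PPV. Metrics with a zero denominator are undefined (NaN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "f1")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        for name in ("tp", "fn", "tn", "fp"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def diseased(self) -> int:
        return self.tp + self.fn

    @property
    def nondiseased(self) -> int:
        return self.tn + self.fp


@dataclass
class DiagnosticPerformance:
    """The five headline metrics, as fractions in [0, 1] (NaN = undefined),
    with optional 95% CI per metric."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}

    def as_percent(self, decimals: int = 1) -> dict[str, float]:
        """Metrics as percentages rounded half-up (matching report tables)."""
        return {m: round_half_up(100 * getattr(self, m), decimals) for m in METRIC_NAMES}


def round_half_up(x: float, decimals: int = 1) -> float:
    if np.isnan(x):
        return float("nan")
    factor = 10.0 ** decimals
    return float(np.floor(x * factor + 0.5) / factor)


def confusion_from_pairs(predictions: Sequence, truths: Sequence) -> ConfusionMatrix:
    """Tally boolean predictions against boolean truths."""
    pred = np.asarray(predictions, dtype=bool)
    truth = np.asarray(truths, dtype=bool)
    if pred.shape != truth.shape or pred.ndim != 1 or len(pred) < 1:
        raise ValueError("predictions and truths must be equal-length 1-D, n >= 1")
    return ConfusionMatrix(
        tp=int(np.sum(pred & truth)),
        fn=int(np.sum(~pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
        fp=int(np.sum(pred & ~truth)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def f_beta_score(ppv: float, sensitivity: float, beta: float = 1.0) -> float:
    """F_beta from PPV and sensitivity; NaN when both are zero or either is NaN."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if np.isnan(ppv) or np.isnan(sensitivity):
        return float("nan")
    denom = beta**2 * ppv + sensitivity
    if denom == 0:
        return float("nan")
    return (1 + beta**2) * ppv * sensitivity / denom


def performance_from_confusion(cm: ConfusionMatrix) -> DiagnosticPerformance:
    """Sensitivity, specificity, PPV, NPV and F1 from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("all-zero confusion matrix")
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    return DiagnosticPerformance(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        f1=f_beta_score(ppv, sens, 1.0),
    )


def bootstrap_ci(
    records,
    metric: Callable,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile-bootstrap CI of ``metric`` over resampled records.

    ``records`` is indexable (ndarray, DataFrame, or a tuple of equal-length
    arrays resampled jointly); ``metric`` maps a resample to a float.
    Resamples on which the metric is undefined (NaN) are dropped with a
    logged count. Percentiles use linear interpolation between order
    statistics. Reproducible given ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if B < 2:
        raise ValueError("B must be >= 2")
    n = _n_records(records)
    if n < 2:
        raise ValueError("need >= 2 records to bootstrap")
    stats_ = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        stats_[b] = metric(_take(records, idx))
    defined = stats_[~np.isnan(stats_)]
    n_dropped = B - len(defined)
    if n_dropped:
        logger.info("bootstrap_ci: dropped %d/%d undefined resamples", n_dropped, B)
    if len(defined) == 0:
        raise ValueError("metric undefined on every bootstrap resample")
    lo, hi = np.percentile(defined, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _n_records(records) -> int:
    if isinstance(records, tuple):
        return len(records[0])
    return len(records)


def _take(records, idx):
    if isinstance(records, tuple):
        return tuple(np.asarray(a)[idx] for a in records)
    if hasattr(records, "iloc"):
        return records.iloc[idx]
    return np.asarray(records)[idx]


def _metric_on_pairs(name: str) -> Callable:
    def fn(resample):
        preds, truths = resample
        cm = confusion_from_pairs(preds, truths)
        return getattr(performance_from_confusion(cm), name)

    return fn


def performance_with_ci(
    predictions,
    truths,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> DiagnosticPerformance:
    """Point metrics plus percentile-bootstrap 95% CIs, resampling regions.

    All five metrics are computed on each of the same ``B`` resamples (one
    resampling pass, as when resampling whole records).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pred = np.asarray(predictions, dtype=bool)
    truth = np.asarray(truths, dtype=bool)
    perf = performance_from_confusion(confusion_from_pairs(pred, truth))
    n = len(pred)
    samples = {m: [] for m in METRIC_NAMES}
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        p = performance_from_confusion(confusion_from_pairs(pred[idx], truth[idx]))
        for m in METRIC_NAMES:
            samples[m].append(getattr(p, m))
    for m in METRIC_NAMES:
        vals = np.asarray(samples[m])
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            perf.warnings.append(f"{m}: undefined on all resamples")
            continue
        if len(vals) < B:
            logger.info("performance_with_ci: %s dropped %d undefined resamples", m, B - len(vals))
        lo, hi = np.percentile(vals, [2.5, 97.5])
        point = getattr(perf, m)
        if not np.isnan(point) and not (lo <= point <= hi):
            perf.warnings.append(f"{m}: point estimate outside percentile interval")
        perf.ci[m] = (float(lo), float(hi))
    return perf
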