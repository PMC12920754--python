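"""Region-paired comparison of quantitative cut-off classifiers with expert
visual assessment: McNemar tests on sensitivity and specificity, with
Benjamini-Hochberg false-discovery-rate adjustment across the batch.

Both methods are evaluated on the identical set of regions (those with both a
quantitative prediction and a visual classification). The sensitivity
comparison uses only truth-positive regions, the specificity comparison only
truth-negative regions; in each stratum McNemar's test depends solely on the
discordant counts b (quantitative correct, visual wrong) and c (visual
correct, quantitative wrong).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metrics import DiagnosticPerformance, confusion_from_pairs, performance_with_ci

logger = logging.getLogger(__name__)

#: discordant-pair count at which the exact binomial test switches to the
#: continuity-corrected chi-square approximation
EXACT_THRESHOLD = 25


def pair_on_regions(
    quant: pd.DataFrame, visual: pd.DataFrame, truths: pd.DataFrame
) -> pd.DataFrame:
    """Intersect quantitative predictions and visual classifications by
    (patient_id, region).

    Each input frame needs columns ``patient_id``, ``region`` and its payload
    (``prediction`` / ``visual`` / ``malignant``). Regions lacking either
    prediction are excluded with a logged count; the output N is the
    per-measure paired N reported in the tables.
    """
    key = ["patient_id", "region"]
    q = quant.dropna(subset=["prediction"])[key + ["prediction"]]
    v = visual.dropna(subset=["visual"])[key + ["visual"]]
    t = truths[key + ["malignant"]]
    merged = q.merge(v, on=key).merge(t, on=key)
    n_excluded = max(len(q), len(v)) - len(merged)
    if len(merged) == 0:
        logger.warning("pair_on_regions: no overlapping regions")
    elif n_excluded:
        logger.info("pair_on_regions: excluded %d unpaired regions", n_excluded)
    out = merged.rename(columns={"malignant": "truth", "prediction": "quant"})
    out["truth"] = out["truth"].astype(bool)
    out["quant"] = out["quant"].astype(bool)
    out["visual"] = out["visual"].astype(bool)
    return out.reset_index(drop=True)


def mcnemar_from_counts(b: int, c: int, exact_threshold: int = EXACT_THRESHOLD) -> float:
    """Two-sided McNemar p-value from the discordant counts.

    Exact binomial (2 * Binom(min(b,c); b+c, 1/2) lower tail, capped at 1)
    when b + c < ``exact_threshold``; otherwise chi-square with continuity
    correction, (|b-c| - 1)^2 / (b+c) on 1 df. b = c = 0 gives p = 1.
    """
    b, c = int(b), int(c)
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    if n < exact_threshold:
        p = 2.0 * stats.binom.cdf(min(b, c), n, 0.5)
        return float(min(p, 1.0))
    chi2 = (abs(b - c) - 1) ** 2 / n
    return float(stats.chi2.sf(chi2, df=1))


def mcnemar_test(paired_outcomes, exact_threshold: int = EXACT_THRESHOLD) -> float:
    """McNemar p from a list of (method A correct?, method B correct?) pairs."""
    arr = np.asarray(paired_outcomes, dtype=bool)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 1:
        raise ValueError("need >= 1 (A correct, B correct) pairs")
    b = int(np.sum(arr[:, 0] & ~arr[:, 1]))
    c = int(np.sum(~arr[:, 0] & arr[:, 1]))
    return mcnemar_from_counts(b, c, exact_threshold)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, position-preserving.

    NaN entries (absent tests) are passed through untouched.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


@dataclass
class ComparisonResult:
    """Quantitative-vs-visual comparison on one measure's paired regions."""

    measure: str
    n: int
    quant_performance: DiagnosticPerformance
    visual_performance: DiagnosticPerformance
    quant_confusion: object
    visual_confusion: object
    mcnemar_sensitivity_p: float
    mcnemar_specificity_p: float
    discordant_sensitivity: tuple[int, int] = (0, 0)
    discordant_specificity: tuple[int, int] = (0, 0)
    adjusted_sensitivity_p: float = float("nan")
    adjusted_specificity_p: float = float("nan")
    warnings: list[str] = field(default_factory=list)

    def significance_flags(self, alpha: float = 0.05) -> dict[str, bool]:
        return {
            "sensitivity": bool(self.adjusted_sensitivity_p < alpha),
            "specificity": bool(self.adjusted_specificity_p < alpha),
        }


def compare_quant_vs_visual(
    pairs: pd.DataFrame, measure: str = "", B: int = 1000, seed=None
) -> ComparisonResult:
    """Metrics with bootstrap CIs for both methods on the identical region
    set, plus McNemar p-values for sensitivity (truth-positives) and
    specificity (truth-negatives). FDR adjustment is applied afterwards
    across the batch via :func:`adjust_comparison_family`."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth = pairs["truth"].to_numpy(dtype=bool)
    quant = pairs["quant"].to_numpy(dtype=bool)
    visual = pairs["visual"].to_numpy(dtype=bool)

    warnings = []
    pos, neg = truth, ~truth
    if pos.any():
        b_s = int(np.sum((quant == truth)[pos] & (visual != truth)[pos]))
        c_s = int(np.sum((quant != truth)[pos] & (visual == truth)[pos]))
        p_sens = mcnemar_from_counts(b_s, c_s)
    else:
        b_s = c_s = 0
        p_sens = float("nan")
        warnings.append("no truth-positive pairs: sensitivity test absent")
        logger.warning("compare_quant_vs_visual[%s]: no truth-positive pairs", measure)
    if neg.any():
        b_p = int(np.sum((quant == truth)[neg] & (visual != truth)[neg]))
        c_p = int(np.sum((quant != truth)[neg] & (visual == truth)[neg]))
        p_spec = mcnemar_from_counts(b_p, c_p)
    else:
        b_p = c_p = 0
        p_spec = float("nan")
        warnings.append("no truth-negative pairs: specificity test absent")
        logger.warning("compare_quant_vs_visual[%s]: no truth-negative pairs", measure)

    return ComparisonResult(
        measure=measure,
        n=len(pairs),
        quant_performance=performance_with_ci(quant, truth, B=B, seed=rng),
        visual_performance=performance_with_ci(visual, truth, B=B, seed=rng),
        quant_confusion=confusion_from_pairs(quant, truth),
        visual_confusion=confusion_from_pairs(visual, truth),
        mcnemar_sensitivity_p=p_sens,
        mcnemar_specificity_p=p_spec,
        discordant_sensitivity=(b_s, c_s),
        discordant_specificity=(b_p, c_p),
        warnings=warnings,
    )


def adjust_comparison_family(results: list[ComparisonResult]) -> list[ComparisonResult]:
    """BH-adjust all McNemar p-values of a run (every measure x
    {sensitivity, specificity}) as one family."""
    raw = []
    for r in results:
        raw.extend([r.mcnemar_sensitivity_p, r.mcnemar_specificity_p])
    adj = fdr_adjust(raw)
    for i, r in enumerate(results):
        r.adjusted_sensitivity_p = float(adj[2 * i])
        r.adjusted_specificity_p = float(adj[2 * i + 1])
    return results


class QuantVisualComparison:
    """Model-style wrapper: paired records in, ComparisonResult out."""

    def __init__(self, pairs: pd.DataFrame, measure: str = ""):
        required = {"truth", "quant", "visual"}
        if not required <= set(pairs.columns):
            raise ValueError(f"pairs frame must have columns {sorted(required)}")
        self.pairs = pairs
        self.measure = measure
        self.nobs = len(pairs)

    def fit(self, B: int = 1000, seed=None) -> ComparisonResult:
        return compare_quant_vs_visual(self.pairs, measure=self.measure, B=B, seed=seed)


def comparison_summary(result: ComparisonResult) -> str:
    qs, vs = result.quant_performance.as_percent(), result.visual_performance.as_percent()
    lines = [
        f"Quantitative vs visual ({result.measure}), N = {result.n} paired regions",
        f"  {'metric':>12} {'quant':>8} {'visual':>8}",
    ]
    for m in ("sensitivity", "specificity", "ppv", "npv", "f1"):
        lines.append(f"  {m:>12} {qs[m]:>7.1f}% {vs[m]:>7.1f}%")
    lines.append(
        f"  McNemar p (sens) = {result.mcnemar_sensitivity_p:.4g}"
        f" [adj {result.adjusted_sensitivity_p:.4g}],"
        f" (spec) = {result.mcnemar_specificity_p:.4g}"
        f" [adj {result.adjusted_specificity_p:.4g}]"
    )
    return "\n".join(lines)
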