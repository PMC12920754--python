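"""End-to-end pipeline: generate/load -> fuse -> analyse -> compare -> report.

``run_analysis`` composes the whole analysis on one cohort bundle and writes
the report CSVs plus a JSON manifest recording the master seed and every
configurable default in force. Randomness uses one master seed with named
substreams per stage, so e.g. changing the bootstrap replicate count does not
perturb the simulation stream.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fusion, io, simulate, stats
from .compare import adjust_comparison_family, compare_quant_vs_visual, pair_on_regions
from .cutpoint import DEFAULT_BETA_GRID, CutpointModel
from .metrics import round_half_up

logger = logging.getLogger(__name__)

_SUBSTREAMS = {"simulate": 0, "bootstrap": 1, "extra": 2}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child generator of the master seed."""
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return np.random.default_rng(children[_SUBSTREAMS[name]])


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    simulation: simulate.SimulationConfig | None = None
    data_dir: str | None = None
    measures: tuple[str, ...] = tuple(fusion.MEASURE_REGISTRY)
    beta: float = 1.0
    beta_grid: tuple[float, ...] = DEFAULT_BETA_GRID
    bootstrap_B: int = 1000
    seed: int = 0
    loocv_unit: str = "region"
    visual_policy: str = "max"
    out_dir: str = "nodalcut_out"

    def __post_init__(self):
        if self.simulation is None and self.data_dir is None:
            raise ValueError("either a simulation config or a data directory is required")
        unknown = [m for m in self.measures if m not in fusion.MEASURE_REGISTRY]
        if unknown:
            raise ValueError(f"unknown measures {unknown}")


@dataclass
class ReportBundle:
    comparison: pd.DataFrame
    betasweep: pd.DataFrame
    group_stats: pd.DataFrame
    correlations: pd.DataFrame
    roc_points: pd.DataFrame
    icc: pd.DataFrame
    manifest: dict
    region_table: pd.DataFrame
    comparisons: list = field(default_factory=list)
    log_lines: list[str] = field(default_factory=list)


def _ci_str(ci: tuple[float, float] | None) -> str:
    if ci is None:
        return ""
    return f"{round_half_up(100 * ci[0]):.1f}-{round_half_up(100 * ci[1]):.1f}"


def _perf_columns(perf) -> dict:
    out = {}
    pct = perf.as_percent()
    for m in ("sensitivity", "specificity", "ppv", "npv", "f1"):
        out[m] = pct[m]
        out[f"{m}_ci"] = _ci_str(perf.ci.get(m))
    return out


def run_analysis(config: RunConfig) -> ReportBundle:
    """Run the full pipeline and write the report bundle to ``out_dir``."""
    log_lines = [
        "stage=config "
        f"seed={config.seed} beta={config.beta} bootstrap_B={config.bootstrap_B} "
        f"loocv_unit={config.loocv_unit} visual_policy={config.visual_policy} "
        "fdr_family=all_mcnemar_tests_in_run tie_break=specificity_then_conservative_cutoff "
        "bootstrap_unit=region percentile=linear_interpolation",
    ]

    # --- inputs ---------------------------------------------------------
    if config.simulation is not None:
        sim_cfg = dataclasses.replace(config.simulation, seed=int(
            substream(config.seed, "simulate").integers(0, 2**31 - 1)
        )) if config.simulation.seed is None else config.simulation
        tables, truth = simulate.generate_cohort(sim_cfg)
        log_lines.append(f"stage=simulate regions={len(tables.histology)} "
                         f"measurement_rows={len(tables.measurements)}")
    else:
        tables = io.read_cohort(config.data_dir)
        truth = None
        log_lines.append(f"stage=load dir={config.data_dir} regions={len(tables.histology)}")

    join = io.join_regions(tables)
    regions = fusion.build_region_table(join, visual_policy=config.visual_policy)
    log_lines.append(
        f"stage=fuse regions={len(regions)} dropped_measurements={join.n_dropped_measurements} "
        f"dropped_visual={join.n_dropped_visual}"
    )

    boot_rng = substream(config.seed, "bootstrap")

    group_rows, corr_rows, roc_rows, icc_rows = [], [], [], []
    comp_rows, sweep_rows, comparisons = [], [], []

    for cohort, cohort_df in regions.groupby("cancer_type", sort=True):
        # --- regional ANOVA on raw measures; pool regions if NS ----------
        pooled = True
        for m in fusion.RAW_MEASURES:
            groups = {
                r: g[m].dropna().to_numpy()
                for r, g in cohort_df.groupby("region")
            }
            groups = {r: v for r, v in groups.items() if len(v) >= 2}
            if len(groups) < 2:
                continue
            res = stats.anova_tukey(groups)
            group_rows.append({
                "cancer_type": cohort, "test": "anova_regions", "measure": m,
                "statistic": res.f_statistic, "pvalue": res.pvalue,
                "adjusted_pvalue": np.nan, "n_x": sum(res.group_sizes.values()), "n_y": 0,
            })
            if res.pvalue < 0.05:
                pooled = False
        log_lines.append(f"stage=region_anova cohort={cohort} pooled={pooled}")

        # --- benign vs malignant Mann-Whitney, FDR family per cohort -----
        mw_idx = []
        for m in config.measures:
            vals = cohort_df[[m, "malignant"]].dropna()
            x = vals.loc[~vals["malignant"], m].to_numpy()
            y = vals.loc[vals["malignant"], m].to_numpy()
            if len(x) == 0 or len(y) == 0:
                continue
            res = stats.mann_whitney(x, y)
            mw_idx.append(len(group_rows))
            group_rows.append({
                "cancer_type": cohort, "test": "mann_whitney_benign_vs_malignant",
                "measure": m, "statistic": res.statistic, "pvalue": res.pvalue,
                "adjusted_pvalue": np.nan, "n_x": res.n_x, "n_y": res.n_y,
            })
        from .compare import fdr_adjust

        adj = fdr_adjust([group_rows[i]["pvalue"] for i in mw_idx])
        for i, a in zip(mw_idx, adj):
            group_rows[i]["adjusted_pvalue"] = float(a)

        # --- Pearson correlations among raw measures ---------------------
        raw = cohort_df[list(fusion.RAW_MEASURES)]
        if raw.notna().sum().min() >= 3:
            r, p_raw, p_adj = stats.pearson_fdr(raw)
            for a in raw.columns:
                for b in raw.columns:
                    if a < b:
                        corr_rows.append({
                            "cancer_type": cohort, "measure_a": a, "measure_b": b,
                            "r": r.loc[a, b], "pvalue": p_raw.loc[a, b],
                            "adjusted_pvalue": p_adj.loc[a, b],
                        })

        # --- ROC curves ---------------------------------------------------
        for m in config.measures:
            sub = cohort_df[[m, "malignant"]].dropna()
            t = sub["malignant"].to_numpy(dtype=bool)
            if not (t.any() and (~t).any()):
                continue
            curve = stats.roc_curve_auc(
                sub[m].to_numpy(), t, fusion.MEASURE_REGISTRY[m]["direction"]
            )
            for fpr, tpr in zip(curve.fpr, curve.tpr):
                roc_rows.append({
                    "cancer_type": cohort, "measure": m, "fpr": float(fpr),
                    "tpr": float(tpr), "auc": curve.auc,
                })

        # --- ICC per modality (nodal) and primary-tumour ADC --------------
        cohort_meas = join.measurements[
            join.measurements["patient_id"].isin(cohort_df["patient_id"])
        ]
        icc_specs = [
            ("FDG_PET", "suvmax", None),
            ("FEC_PET", "suvmax", None),
            ("DWMRI", "adc_mean", None),
            ("DWMRI", "adc_mean", io.PRIMARY_TUMOUR),
        ]
        for modality, measure, region in icc_specs:
            mat = stats.reader_matrix(cohort_meas, modality, measure, region=region)
            try:
                res = stats.icc_oneway(mat)
            except ValueError as e:
                logger.info("icc skipped (%s %s %s %s): %s", cohort, modality, measure, region, e)
                continue
            icc_rows.append({
                "cancer_type": cohort,
                "modality": modality + ("_PT" if region == io.PRIMARY_TUMOUR else ""),
                "measure": measure, "icc": res.icc, "ci_low": res.ci_low,
                "ci_high": res.ci_high, "n_subjects": res.n_subjects,
                "k_raters": res.k_raters,
            })

        # --- cut-points, LOOCV, paired comparison with visual -------------
        cohort_comparisons = []
        for m in config.measures:
            visual_col = fusion.MEASURE_REGISTRY[m]["visual"]
            sub = cohort_df[["patient_id", "region", "malignant", m, visual_col]]
            sub = sub[sub[m].notna()]
            t = sub["malignant"].to_numpy(dtype=bool)
            if len(sub) < 3 or not (t.any() and (~t).any()):
                logger.info("measure %s skipped in cohort %s (insufficient data)", m, cohort)
                continue
            model = CutpointModel.from_dataframe(sub, m)
            cv = model.fit_loocv(beta=config.beta, bootstrap_B=config.bootstrap_B, seed=boot_rng)

            quant = pd.DataFrame({
                "patient_id": sub["patient_id"].to_numpy(),
                "region": sub["region"].to_numpy(),
                "prediction": [p.prediction for p in cv.predictions],
            })
            visual_df = pd.DataFrame({
                "patient_id": sub["patient_id"].to_numpy(),
                "region": sub["region"].to_numpy(),
                "visual": sub[visual_col].to_numpy(),
            })
            truths_df = sub[["patient_id", "region", "malignant"]]
            pairs = pair_on_regions(quant, visual_df, truths_df)
            if len(pairs) == 0:
                continue
            comp = compare_quant_vs_visual(pairs, measure=m, B=config.bootstrap_B, seed=boot_rng)
            comp.cancer_type = cohort
            comp.median_cutoff = cv.median_cutoff
            cohort_comparisons.append(comp)

            sweep = model.beta_sweep(
                config.beta_grid, bootstrap_B=config.bootstrap_B, seed=boot_rng
            )
            sweep.insert(0, "cancer_type", cohort)
            sweep.insert(1, "modality", fusion.MEASURE_REGISTRY[m]["modality"])
            sweep_rows.append(sweep)
            log_lines.append(
                f"stage=cutpoint cohort={cohort} measure={m} n={len(sub)} "
                f"median_cutoff={cv.median_cutoff:g} paired_n={len(pairs)}"
            )

        adjust_comparison_family(cohort_comparisons)
        comparisons.extend(cohort_comparisons)
        for comp in cohort_comparisons:
            for method, perf, cm in (
                ("quantitative", comp.quant_performance, comp.quant_confusion),
                ("visual", comp.visual_performance, comp.visual_confusion),
            ):
                comp_rows.append({
                    "cancer_type": comp.cancer_type, "measure": comp.measure,
                    "method": method,
                    "oc": comp.median_cutoff if method == "quantitative" else np.nan,
                    "n": comp.n, "tp": cm.tp, "fn": cm.fn, "tn": cm.tn, "fp": cm.fp,
                    **_perf_columns(perf),
                    "mcnemar_sensitivity_p": comp.mcnemar_sensitivity_p,
                    "mcnemar_specificity_p": comp.mcnemar_specificity_p,
                    "adjusted_sensitivity_p": comp.adjusted_sensitivity_p,
                    "adjusted_specificity_p": comp.adjusted_specificity_p,
                })

    bundle = ReportBundle(
        comparison=pd.DataFrame(comp_rows),
        betasweep=(pd.concat(sweep_rows, ignore_index=True) if sweep_rows else pd.DataFrame()),
        group_stats=pd.DataFrame(group_rows),
        correlations=pd.DataFrame(corr_rows),
        roc_points=pd.DataFrame(roc_rows),
        icc=pd.DataFrame(icc_rows),
        manifest={
            "seed": config.seed,
            "beta": config.beta,
            "beta_grid": list(config.beta_grid),
            "bootstrap_B": config.bootstrap_B,
            "loocv_unit": config.loocv_unit,
            "visual_policy": config.visual_policy,
            "measures": list(config.measures),
            "n_regions": int(len(regions)),
            "fdr_family": "all McNemar tests (measure x {sensitivity, specificity}) per cohort run",
            "tie_break": "max F_beta, then max specificity, then conservative cutoff",
            "bootstrap_unit": "region",
        },
        region_table=regions,
        comparisons=comparisons,
        log_lines=log_lines,
    )
    _write_bundle(bundle, config.out_dir)
    if truth is not None:
        simulate.write_truth(truth, config.out_dir)
    return bundle


def _write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.comparison.to_csv(out / "comparison.csv", index=False)
    bundle.betasweep.to_csv(out / "betasweep.csv", index=False)
    bundle.group_stats.to_csv(out / "group_stats.csv", index=False)
    bundle.correlations.to_csv(out / "correlations.csv", index=False)
    bundle.roc_points.to_csv(out / "roc_points.csv", index=False)
    bundle.icc.to_csv(out / "icc.csv", index=False)
    fusion.write_region_table(bundle.region_table, out / "regions_analysis.csv")
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True))
    (out / "run_log.txt").write_text("\n".join(bundle.log_lines) + "\n")


def make_table1(comparison: pd.DataFrame) -> pd.DataFrame:
    """Performance table: one quantitative row per measure with its matched
    visual row (OC, N, counts, five metrics with CIs; percentages at 1 d.p.)."""
    if len(comparison) == 0:
        raise ValueError("no comparison results")
    cols = ["cancer_type", "measure", "method", "oc", "n", "tp", "fn", "tn", "fp"]
    metric_cols = []
    for m in ("sensitivity", "specificity", "ppv", "npv", "f1"):
        metric_cols.append(m)
        metric_cols.append(f"{m}_ci")
    out = comparison[cols + metric_cols + ["adjusted_sensitivity_p", "adjusted_specificity_p"]].copy()
    for m in ("sensitivity", "specificity", "ppv", "npv", "f1"):
        flagged = out[f"{m}_ci"].isin(["", None]) | out[f"{m}_ci"].isna()
        out[f"{m}_ci"] = out[f"{m}_ci"].where(~flagged, "CI unavailable")
    return out


def make_table2(icc: pd.DataFrame) -> pd.DataFrame:
    """Interobserver-agreement table: cancer x modality x measure with ICC and
    95% CI, signed and formatted to 3 d.p."""
    if len(icc) == 0:
        raise ValueError("no ICC results")
    out = icc.copy()
    out["icc_fmt"] = out["icc"].map(lambda v: f"{v:.3f}")
    out["ci_fmt"] = out.apply(lambda r: f"{r['ci_low']:.3f} to {r['ci_high']:.3f}", axis=1)
    return out[["cancer_type", "modality", "measure", "icc_fmt", "ci_fmt",
                "n_subjects", "k_raters"]]
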