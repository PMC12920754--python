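"""Reader fusion, ratio features (NTR, STAR), and visual binarisation.

Fusion rule for nodal measurements: where both central readers measured a
region their readings are averaged; where only one did, that reading is used;
where neither did, the external third PET reader's measurement is used.
Primary-tumour values use the mean of the two central readers only (no
external fallback).

Derived measures:

* NTR (nodal-to-tumour ratio): nodal value / primary-tumour value of the same
  modality and measure;
* STAR (SUV-to-ADC ratio): nodal SUV_max / nodal ADC_mean (ADC on the
  1e-6 mm^2/s numeric scale), for each PET modality.

Visual positivity: a 6-point confidence score of 5 or 6 is classed malignant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CENTRAL_READERS, EXTERNAL_READER, PRIMARY_TUMOUR, RegionJoin

logger = logging.getLogger(__name__)

#: analysis measures: column -> (modality, nodal source, direction, matched visual column)
MEASURE_REGISTRY: dict[str, dict] = {
    "fdg_suvmax": {"modality": "FDG_PET", "direction": "greater_equal", "visual": "visual_fdg"},
    "fec_suvmax": {"modality": "FEC_PET", "direction": "greater_equal", "visual": "visual_fec"},
    "adc_mean": {"modality": "DWMRI", "direction": "less_equal", "visual": "visual_dwmri"},
    "fdg_ntr": {"modality": "FDG_PET", "direction": "greater_equal", "visual": "visual_fdg"},
    "fec_ntr": {"modality": "FEC_PET", "direction": "greater_equal", "visual": "visual_fec"},
    "adc_ntr": {"modality": "DWMRI", "direction": "less_equal", "visual": "visual_dwmri"},
    "fdg_star": {"modality": "FDG_PET", "direction": "greater_equal", "visual": "visual_fdg"},
    "fec_star": {"modality": "FEC_PET", "direction": "greater_equal", "visual": "visual_fec"},
}

RAW_MEASURES = ("fdg_suvmax", "fec_suvmax", "adc_mean")
VISUAL_COLUMNS = ("visual_fdg", "visual_fec", "visual_dwmri")
VISUAL_BY_MODALITY = {"FDG_PET": "visual_fdg", "FEC_PET": "visual_fec", "DWMRI": "visual_dwmri"}

_RAW_SOURCE = {
    "fdg_suvmax": ("FDG_PET", "suvmax"),
    "fec_suvmax": ("FEC_PET", "suvmax"),
    "adc_mean": ("DWMRI", "adc_mean"),
}

VISUAL_POSITIVE_MIN = 5


@dataclass(frozen=True)
class FusionPolicy:
    central_readers: tuple[str, str] = CENTRAL_READERS
    external_reader: str = EXTERNAL_READER

    def __post_init__(self):
        if self.external_reader in self.central_readers:
            raise ValueError("central and external reader sets must be disjoint")


def fuse_readers(values: Mapping[str, float], policy: FusionPolicy = FusionPolicy()) -> float | None:
    """Fuse per-reader nodal readings into one value (or None if none exist)."""
    central = [values[r] for r in policy.central_readers if r in values and values[r] is not None]
    if central:
        return float(np.mean(central))
    ext = values.get(policy.external_reader)
    return float(ext) if ext is not None else None


def fuse_tumour_readers(
    values: Mapping[str, float], policy: FusionPolicy = FusionPolicy()
) -> float | None:
    """Primary-tumour fusion: mean of central readers only, no external fallback."""
    central = [values[r] for r in policy.central_readers if r in values and values[r] is not None]
    return float(np.mean(central)) if central else None


def compute_ntr(nodal_value: float | None, tumour_value: float | None) -> float | None:
    """Nodal-to-tumour ratio; absent when either operand is absent or
    the tumour value is non-positive."""
    if nodal_value is None or tumour_value is None:
        return None
    if tumour_value <= 0:
        logger.warning("NTR skipped: non-positive tumour value %r", tumour_value)
        return None
    return float(nodal_value) / float(tumour_value)


def compute_star(suvmax: float | None, adc_mean: float | None) -> float | None:
    """SUV_max-to-ADC_mean ratio (ADC on the 1e-6 mm^2/s numeric scale)."""
    if suvmax is None or adc_mean is None:
        return None
    if adc_mean <= 0:
        logger.warning("STAR skipped: non-positive ADC %r", adc_mean)
        return None
    return float(suvmax) / float(adc_mean)


def binarize_visual(score: int) -> bool:
    """Scores of 5 or 6 are classed malignant."""
    if not 1 <= int(score) <= 6:
        raise ValueError(f"visual score {score} outside [1, 6]")
    return int(score) >= VISUAL_POSITIVE_MIN


def combine_visual_readers(
    scores: Mapping[str, int], policy: str = "max"
) -> bool | None:
    """Combine per-reader confidence scores into one region classification.

    Policies: ``"max"`` (positive iff the most suspicious reader scored >= 5,
    the default), ``"mean"`` (mean score rounded half-up, then >= 5), or a
    reader id (use that reader's score only; absent if that reader did not
    score).
    """
    if not scores:
        return None
    vals = {r: int(s) for r, s in scores.items() if s is not None}
    if not vals:
        return None
    if policy == "max":
        return binarize_visual(max(vals.values()))
    if policy == "mean":
        m = int(np.floor(np.mean(list(vals.values())) + 0.5))
        return binarize_visual(min(6, max(1, m)))
    if policy in vals:
        return binarize_visual(vals[policy])
    if policy in ("central_1", "central_2", "external_3"):
        return None
    raise ValueError(f"unknown visual combination policy {policy!r}")


def _fused_lookup(meas: pd.DataFrame, tumour: bool, policy: FusionPolicy) -> dict:
    """(patient, region or patient-only, modality, measure) -> fused value."""
    fuse = fuse_tumour_readers if tumour else fuse_readers
    out = {}
    group_cols = ["patient_id", "modality", "measure"] if tumour else [
        "patient_id", "region", "modality", "measure"
    ]
    for key, grp in meas.groupby(group_cols, sort=False):
        per_reader = dict(zip(grp["reader"], grp["value"]))
        out[key] = fuse(per_reader, policy)
    return out


def build_region_table(
    join: RegionJoin,
    policy: FusionPolicy = FusionPolicy(),
    visual_policy: str = "max",
) -> pd.DataFrame:
    """Assemble the analysis-ready wide table: one row per nodal region.

    Columns: identifiers and truth; fused raw measures; fused primary-tumour
    measures (``pt_`` prefix); derived NTR/STAR measures; per-modality visual
    classifications. Absent values are NaN (None for visual booleans).
    """
    meas = join.measurements
    nodal = _fused_lookup(meas[meas["region"] != PRIMARY_TUMOUR], tumour=False, policy=policy)
    pt = _fused_lookup(meas[meas["region"] == PRIMARY_TUMOUR], tumour=True, policy=policy)

    vis_lookup: dict = {}
    for key, grp in join.visual.groupby(["patient_id", "region", "modality"], sort=False):
        vis_lookup[key] = combine_visual_readers(
            dict(zip(grp["reader"], grp["score"])), policy=visual_policy
        )

    rows = []
    for rec in join.regions.itertuples(index=False):
        row: dict = {
            "patient_id": rec.patient_id,
            "cancer_type": rec.cancer_type,
            "region": rec.region,
            "malignant": bool(rec.malignant),
        }
        fused = {}
        for col, (modality, measure) in _RAW_SOURCE.items():
            fused[col] = nodal.get((rec.patient_id, rec.region, modality, measure))
            row[col] = np.nan if fused[col] is None else fused[col]
            pt_val = pt.get((rec.patient_id, modality, measure))
            row[f"pt_{col}"] = np.nan if pt_val is None else pt_val
        row["fdg_ntr"] = _na(compute_ntr(fused["fdg_suvmax"], pt.get((rec.patient_id, "FDG_PET", "suvmax"))))
        row["fec_ntr"] = _na(compute_ntr(fused["fec_suvmax"], pt.get((rec.patient_id, "FEC_PET", "suvmax"))))
        row["adc_ntr"] = _na(compute_ntr(fused["adc_mean"], pt.get((rec.patient_id, "DWMRI", "adc_mean"))))
        row["fdg_star"] = _na(compute_star(fused["fdg_suvmax"], fused["adc_mean"]))
        row["fec_star"] = _na(compute_star(fused["fec_suvmax"], fused["adc_mean"]))
        for modality, col in VISUAL_BY_MODALITY.items():
            row[col] = vis_lookup.get((rec.patient_id, rec.region, modality))
        rows.append(row)

    df = pd.DataFrame(rows)
    for col in VISUAL_COLUMNS:
        df[col] = df[col].astype(object)
    return df


def _na(v: float | None) -> float:
    return np.nan if v is None else v


def write_region_table(df: pd.DataFrame, path) -> None:
    """Write ``regions_analysis.csv`` with absent values as empty cells."""
    out = df.copy()
    for col in VISUAL_COLUMNS:
        out[col] = out[col].map(lambda v: "" if v is None else int(bool(v)))
    out["malignant"] = out["malignant"].astype(int)
    out.to_csv(path, index=False)
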