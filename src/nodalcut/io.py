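"""Cohort data model: schemas, validation, and delimited-file round trip.

The unit of analysis is the nodal region: one of three lymph-node basins
(left pelvic, right pelvic, para-aortic) per patient, labelled malignant when
at least one resected node from that basin is histologically malignant.
Three long-format tables carry the cohort:

``histology.csv``
    one row per (patient, region) with the histological truth,
``measurements.csv``
    one row per (patient, region, modality, measure, reader) quantitative
    reading; ``region`` may be the sentinel ``primary_tumour``,
``visual.csv``
    one row per (patient, region, modality, reader) 6-point confidence score.

All files are comma-delimited UTF-8 with a header row and dot decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

REGIONS = ("left_pelvic", "right_pelvic", "para_aortic")
PRIMARY_TUMOUR = "primary_tumour"
CANCER_TYPES = ("endometrial", "cervical")
MODALITIES = ("FDG_PET", "FEC_PET", "DWMRI")
PET_MODALITIES = ("FDG_PET", "FEC_PET")
MEASURES = ("suvmax", "adc_mean")
CENTRAL_READERS = ("central_1", "central_2")
EXTERNAL_READER = "external_3"
READERS = CENTRAL_READERS + (EXTERNAL_READER,)

HISTOLOGY_COLUMNS = ("patient_id", "cancer_type", "region", "malignant", "n_nodes_retrieved")
MEASUREMENT_COLUMNS = ("patient_id", "region", "modality", "measure", "reader", "value")
VISUAL_COLUMNS = ("patient_id", "region", "modality", "reader", "score")

FILE_NAMES = {
    "histology": "histology.csv",
    "measurements": "measurements.csv",
    "visual": "visual.csv",
}


class CohortValidationError(ValueError):
    """Raised when a cohort file violates the schema; names file and row."""

    def __init__(self, message: str, file: str | None = None, row: int | None = None):
        loc = ""
        if file is not None:
            loc = f" [{file}" + (f", line {row}]" if row is not None else "]")
        super().__init__(message + loc)
        self.file = file
        self.row = row


@dataclass
class CohortTables:
    """The three validated long-format tables of a cohort."""

    histology: pd.DataFrame
    measurements: pd.DataFrame
    visual: pd.DataFrame

    def __eq__(self, other):  # field-for-field equality
        if not isinstance(other, CohortTables):
            return NotImplemented
        return (
            self.histology.equals(other.histology)
            and self.measurements.equals(other.measurements)
            and self.visual.equals(other.visual)
        )


@dataclass
class RegionJoin:
    """Histology-anchored join: one row per histology record plus the
    measurement/visual rows that have a matching histology key.

    Primary-tumour measurement rows are retained for every patient present in
    the histology table (they are patient-level, not region-level).
    """

    regions: pd.DataFrame
    measurements: pd.DataFrame
    visual: pd.DataFrame
    n_dropped_measurements: int
    n_dropped_visual: int


def _line(idx: int) -> int:
    # +2: header line plus 1-based indexing
    return int(idx) + 2


def _require_columns(df: pd.DataFrame, required, file: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required column(s) {missing}", file=file)


def _check_labels(series: pd.Series, allowed, file: str, what: str) -> None:
    bad = ~series.isin(allowed)
    if bad.any():
        i = int(series.index[bad][0])
        raise CohortValidationError(
            f"unknown {what} {series.iloc[series.index.get_loc(i)]!r}", file=file, row=_line(i)
        )


def _validate_histology(df: pd.DataFrame, file: str = "histology.csv") -> pd.DataFrame:
    _require_columns(df, HISTOLOGY_COLUMNS[:4], file)
    df = df.copy()
    _check_labels(df["cancer_type"], CANCER_TYPES, file, "cancer_type")
    _check_labels(df["region"], REGIONS, file, "region")
    bad = ~df["malignant"].isin([0, 1, True, False])
    if bad.any():
        raise CohortValidationError(
            "malignant must be 0 or 1", file=file, row=_line(df.index[bad][0])
        )
    df["malignant"] = df["malignant"].astype(bool)
    dup = df.duplicated(subset=["patient_id", "region"])
    if dup.any():
        raise CohortValidationError(
            "duplicate (patient_id, region) histology row", file=file, row=_line(df.index[dup][0])
        )
    inconsistent = df.groupby("patient_id")["cancer_type"].nunique() > 1
    if inconsistent.any():
        pid = inconsistent.index[inconsistent][0]
        raise CohortValidationError(f"cancer_type not constant within patient {pid!r}", file=file)
    if "n_nodes_retrieved" not in df.columns:
        df["n_nodes_retrieved"] = pd.array([pd.NA] * len(df), dtype="Int64")
    else:
        df["n_nodes_retrieved"] = df["n_nodes_retrieved"].astype("Int64")
        if (df["n_nodes_retrieved"].dropna() < 0).any():
            bad = df.index[df["n_nodes_retrieved"] < 0][0]
            raise CohortValidationError("n_nodes_retrieved < 0", file=file, row=_line(bad))
    df["patient_id"] = df["patient_id"].astype(str)
    return df.reset_index(drop=True)[list(HISTOLOGY_COLUMNS)]


def _validate_measurements(df: pd.DataFrame, file: str = "measurements.csv") -> pd.DataFrame:
    _require_columns(df, MEASUREMENT_COLUMNS, file)
    df = df.copy()
    _check_labels(df["region"], REGIONS + (PRIMARY_TUMOUR,), file, "region")
    _check_labels(df["modality"], MODALITIES, file, "modality")
    _check_labels(df["measure"], MEASURES, file, "measure")
    _check_labels(df["reader"], READERS, file, "reader")
    df["value"] = pd.to_numeric(df["value"])
    bad = ~(df["value"] > 0)
    if bad.any():
        raise CohortValidationError(
            f"value must be > 0 (got {df.loc[df.index[bad][0], 'value']})",
            file=file,
            row=_line(df.index[bad][0]),
        )
    # a DW-MRI reading is an ADC reading and vice versa
    mismatch = (df["modality"] == "DWMRI") != (df["measure"] == "adc_mean")
    if mismatch.any():
        raise CohortValidationError(
            "modality DWMRI must pair with measure adc_mean (and only DWMRI may)",
            file=file,
            row=_line(df.index[mismatch][0]),
        )
    ext_bad = (df["reader"] == EXTERNAL_READER) & ~df["modality"].isin(PET_MODALITIES)
    if ext_bad.any():
        raise CohortValidationError(
            f"reader {EXTERNAL_READER} only valid for PET modalities",
            file=file,
            row=_line(df.index[ext_bad][0]),
        )
    dup = df.duplicated(subset=["patient_id", "region", "modality", "measure", "reader"])
    if dup.any():
        raise CohortValidationError(
            "duplicate measurement row for (patient, region, modality, measure, reader)",
            file=file,
            row=_line(df.index[dup][0]),
        )
    df["patient_id"] = df["patient_id"].astype(str)
    df["value"] = df["value"].astype(float)
    return df.reset_index(drop=True)[list(MEASUREMENT_COLUMNS)]


def _validate_visual(df: pd.DataFrame, file: str = "visual.csv") -> pd.DataFrame:
    _require_columns(df, VISUAL_COLUMNS, file)
    df = df.copy()
    _check_labels(df["region"], REGIONS, file, "region")
    _check_labels(df["modality"], MODALITIES, file, "modality")
    _check_labels(df["reader"], READERS, file, "reader")
    score = pd.to_numeric(df["score"])
    bad = ~score.isin(range(1, 7))
    if bad.any():
        raise CohortValidationError(
            f"score outside [1, 6] (got {score.iloc[df.index.get_loc(df.index[bad][0])]})",
            file=file,
            row=_line(df.index[bad][0]),
        )
    df["score"] = score.astype(int)
    df["patient_id"] = df["patient_id"].astype(str)
    return df.reset_index(drop=True)[list(VISUAL_COLUMNS)]


def _resolve_paths(paths) -> dict[str, Path]:
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        return {k: base / v for k, v in FILE_NAMES.items()}
    return {k: Path(v) for k, v in dict(paths).items()}


def read_cohort(paths: Mapping[str, str | Path] | str | Path) -> CohortTables:
    """Read and validate the three cohort tables.

    Parameters
    ----------
    paths
        Either a directory containing ``histology.csv``, ``measurements.csv``
        and ``visual.csv``, or a mapping with keys ``histology``,
        ``measurements``, ``visual``.

    Raises
    ------
    CohortValidationError
        On any schema violation, naming the offending file and line.
    """
    resolved = _resolve_paths(paths)
    for key in FILE_NAMES:
        if key not in resolved:
            raise CohortValidationError(f"no path given for {key!r} table")
        if not resolved[key].exists():
            raise CohortValidationError(f"file not found: {resolved[key]}", file=str(resolved[key]))
    # round_trip float parsing keeps write->read lossless to the last ULP
    hist = pd.read_csv(resolved["histology"], float_precision="round_trip")
    meas = pd.read_csv(resolved["measurements"], float_precision="round_trip")
    vis = pd.read_csv(resolved["visual"], float_precision="round_trip")
    return CohortTables(
        histology=_validate_histology(hist, file=str(resolved["histology"])),
        measurements=_validate_measurements(meas, file=str(resolved["measurements"])),
        visual=_validate_visual(vis, file=str(resolved["visual"])),
    )


def validate_cohort(tables: CohortTables) -> CohortTables:
    """Validate in-memory tables (same checks as :func:`read_cohort`)."""
    return CohortTables(
        histology=_validate_histology(tables.histology),
        measurements=_validate_measurements(tables.measurements),
        visual=_validate_visual(tables.visual),
    )


def write_cohort(tables: CohortTables, out_dir: str | Path) -> dict[str, Path]:
    """Write the three tables as CSV; inverse of :func:`read_cohort`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in FILE_NAMES.items()}
    hist = tables.histology.copy()
    hist["malignant"] = hist["malignant"].astype(int)
    hist.to_csv(paths["histology"], index=False)
    tables.measurements.to_csv(paths["measurements"], index=False)
    tables.visual.to_csv(paths["visual"], index=False)
    return paths


def join_regions(tables: CohortTables) -> RegionJoin:
    """Anchor measurements and visual scores to histologically verified regions.

    Only reads in regions with corresponding nodal histology enter the
    analysis: the output has exactly one region row per histology row, and
    measurement/visual rows without a histology match are dropped (counted and
    logged, never fatal). Primary-tumour rows are kept for every patient in
    the histology table.
    """
    hist = tables.histology
    keys = set(zip(hist["patient_id"], hist["region"]))
    patients = set(hist["patient_id"])

    meas = tables.measurements
    is_pt = meas["region"] == PRIMARY_TUMOUR
    meas_keep = (
        is_pt & meas["patient_id"].isin(patients)
    ) | pd.Series(list(zip(meas["patient_id"], meas["region"])), index=meas.index).isin(keys)
    n_drop_meas = int((~meas_keep).sum())

    vis = tables.visual
    vis_keep = pd.Series(list(zip(vis["patient_id"], vis["region"])), index=vis.index).isin(keys)
    n_drop_vis = int((~vis_keep).sum())

    if n_drop_meas:
        logger.info("join_regions: dropped %d measurement rows without histology", n_drop_meas)
    if n_drop_vis:
        logger.info("join_regions: dropped %d visual rows without histology", n_drop_vis)

    return RegionJoin(
        regions=hist[["patient_id", "cancer_type", "region", "malignant"]].reset_index(drop=True),
        measurements=meas[meas_keep].reset_index(drop=True),
        visual=vis[vis_keep].reset_index(drop=True),
        n_dropped_measurements=n_drop_meas,
        n_dropped_visual=n_drop_vis,
    )
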