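"""Published reference results from the MAPPING endometrial-cancer cohort.

The study's per-region raw measurements are not public, but its published
performance table prints, for every quantitative measure and its matched
visual-assessment rows, the confusion-matrix quadruple (TP, FN, TN, FP)
alongside the optimal cut-off and the five percentage metrics. Those printed
quadruples are exactly recomputable inputs: they anchor the metric layer and
give the acceptance checks a ground truth that does not depend on the
synthetic generator.

Fields: ``method`` is ``quantitative`` or ``visual``; visual rows are matched
region-for-region to the quantitative measure named in ``measure`` (hence the
same N); ``oc`` is the reported optimal cut-off (absent for visual rows);
percentages are as printed, at 1 decimal place.
"""

from __future__ import annotations

import pandas as pd

_COLUMNS = [
    "modality", "measure", "method", "oc", "n",
    "tp", "fn", "tn", "fp",
    "sensitivity", "specificity", "ppv", "npv", "f1",
]

_ROWS = [
    # modality, measure, method, oc, n, tp, fn, tn, fp, sens, spec, ppv, npv, f1
    ("FDG_PET", "fdg_suvmax", "quantitative", 4.3, 99, 24, 7, 58, 10, 77.4, 85.3, 70.6, 89.2, 73.8),
    ("FDG_PET", "fdg_star", "quantitative", 0.00477, 77, 23, 6, 38, 10, 79.3, 79.2, 69.7, 86.4, 74.2),
    ("FDG_PET", "fdg_ntr", "quantitative", 0.474, 92, 16, 14, 50, 12, 53.3, 80.6, 57.1, 78.1, 55.2),
    ("FEC_PET", "fec_suvmax", "quantitative", 2.7, 41, 8, 4, 27, 2, 66.7, 93.1, 80.0, 87.1, 72.7),
    ("FEC_PET", "fec_star", "quantitative", 0.00226, 28, 9, 2, 12, 5, 81.8, 70.6, 64.3, 85.7, 72.0),
    ("FEC_PET", "fec_ntr", "quantitative", 0.384, 36, 7, 5, 19, 5, 58.3, 79.2, 58.3, 79.2, 58.3),
    ("DWMRI", "adc_mean", "quantitative", 847.0, 107, 24, 6, 35, 42, 80.0, 45.5, 36.4, 85.4, 50.0),
    ("DWMRI", "adc_ntr", "quantitative", 1.55, 80, 22, 3, 12, 43, 88.0, 21.8, 33.8, 80.0, 48.9),
    ("FDG_PET", "fdg_suvmax", "visual", None, 99, 26, 5, 60, 8, 83.9, 88.2, 76.5, 92.3, 80.0),
    ("FDG_PET", "fdg_star", "visual", None, 77, 25, 4, 41, 7, 86.2, 85.4, 78.1, 91.1, 82.0),
    ("FDG_PET", "fdg_ntr", "visual", None, 92, 25, 5, 55, 7, 83.3, 88.7, 78.1, 91.7, 80.6),
    ("FEC_PET", "fec_suvmax", "visual", None, 41, 8, 4, 26, 3, 66.7, 89.7, 72.7, 86.7, 69.6),
    ("FEC_PET", "fec_star", "visual", None, 28, 8, 3, 14, 3, 72.7, 82.4, 72.7, 82.4, 72.7),
    ("FEC_PET", "fec_ntr", "visual", None, 36, 8, 4, 21, 3, 66.7, 87.5, 72.7, 84.0, 69.6),
    ("DWMRI", "adc_mean", "visual", None, 107, 23, 7, 71, 6, 76.7, 92.2, 79.3, 91.0, 78.0),
    ("DWMRI", "adc_ntr", "visual", None, 80, 20, 5, 51, 4, 80.0, 92.7, 83.3, 91.1, 81.6),
]

#: published interobserver ICC(1) values (point, 95% CI) per cohort/modality;
#: PT = primary tumour. Included for qualitative comparison only — they are
#: not recomputable without the raw per-reader measurements.
REFERENCE_ICC = pd.DataFrame(
    [
        ("endometrial", "FDG_PET", "suvmax", 0.976, 0.964, 0.984),
        ("endometrial", "FEC_PET", "suvmax", 0.954, 0.911, 0.979),
        ("endometrial", "DWMRI", "adc_mean", 0.580, 0.385, 0.725),
        ("endometrial", "DWMRI_PT", "adc_mean", 0.781, 0.501, 0.914),
        ("cervical", "FDG_PET", "suvmax", 0.741, 0.442, 0.919),
        ("cervical", "FEC_PET", "suvmax", 0.891, 0.697, 0.974),
        ("cervical", "DWMRI", "adc_mean", 0.477, 0.023, 0.771),
        ("cervical", "DWMRI_PT", "adc_mean", -0.016, -0.648, 0.652),
    ],
    columns=["cancer_type", "modality", "measure", "icc", "ci_low", "ci_high"],
)


def load_reference_performance() -> pd.DataFrame:
    """The published endometrial-cohort performance table as a DataFrame."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)
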