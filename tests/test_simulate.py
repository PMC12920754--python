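"""Synthetic-cohort generator: determinism, configured-target recovery,
visual-score model, and config round trip."""

import dataclasses

import numpy as np
import pytest
from scipy import integrate, stats

from nodalcut import (
    MarkerParams,
    analytic_auc,
    build_region_table,
    generate_cohort,
    generate_visual_scores,
    join_regions,
    mapping_endometrial_like,
    reader_noise_for_icc,
    roc_curve_auc,
    write_cohort,
)
from nodalcut.simulate import (
    SimulationConfig,
    VisualModel,
    config_from_yaml,
    config_to_yaml,
    score_from_latent,
)
from nodalcut.stats import icc_oneway, reader_matrix


def _file_bytes(d):
    return {p.name: p.read_bytes() for p in sorted(d.iterdir())}


def test_same_seed_byte_identical(tmp_path):
    cfg = mapping_endometrial_like(seed=5, n_patients=10)
    for sub in ("a", "b"):
        tables, _ = generate_cohort(cfg)
        write_cohort(tables, tmp_path / sub)
    assert _file_bytes(tmp_path / "a") == _file_bytes(tmp_path / "b")


def test_sidecar_matches_histology(endo_cohort):
    _, tables, truth = endo_cohort
    assert len(truth) == len(tables.histology)
    merged = truth.merge(
        tables.histology, on=["patient_id", "region"], suffixes=("_t", "_h")
    )
    assert len(merged) == len(truth)
    assert (merged["malignant_t"].astype(bool) == merged["malignant_h"]).all()


def test_zero_reader_noise_gives_icc_one():
    cfg = mapping_endometrial_like(seed=2, n_patients=20)
    cfg.reader_noise = {k: 0.0 for k in cfg.reader_noise}
    cfg.central_miss = 0.0
    tables, _ = generate_cohort(cfg)
    mat = reader_matrix(tables.measurements, "FDG_PET", "suvmax")
    res = icc_oneway(mat)
    assert res.icc == pytest.approx(1.0, abs=1e-12)


def test_null_class_separation_gives_chance_auc():
    cfg = mapping_endometrial_like(seed=11, n_patients=667)  # ~2000 regions
    cfg.markers = {
        k: dataclasses.replace(m, malignant_loc=m.benign_loc) for k, m in cfg.markers.items()
    }
    tables, _ = generate_cohort(cfg)
    df = build_region_table(join_regions(tables))
    curve = roc_curve_auc(df["fdg_suvmax"], df["malignant"], "greater_equal")
    assert 0.4 <= curve.auc <= 0.6


def test_endometrial_like_prevalence_at_study_scale():
    # 99 regions; configured region-level prevalence 31/99
    cfg = mapping_endometrial_like(seed=17)
    tables, _ = generate_cohort(cfg)
    assert len(tables.histology) == 99
    frac = tables.histology["malignant"].mean()
    assert 0.25 <= frac <= 0.38


def test_prevalence_and_missingness_within_3_binomial_sd():
    cfg = mapping_endometrial_like(seed=23, n_patients=400)
    tables, truth = generate_cohort(cfg)
    n = len(truth)
    p = 31 / 99
    assert abs(truth["malignant"].mean() - p) <= 3 * np.sqrt(p * (1 - p) / n)

    meas = tables.measurements
    n_pat = cfg.n_patients["endometrial"]
    fec_patients = meas.loc[meas["modality"] == "FEC_PET", "patient_id"].nunique()
    q = cfg.missing_fec_patient
    assert abs((n_pat - fec_patients) / n_pat - q) <= 3 * np.sqrt(q * (1 - q) / n_pat)

    dw = meas[(meas["modality"] == "DWMRI") & (meas["region"] != "primary_tumour")]
    dw_regions = dw[["patient_id", "region"]].drop_duplicates().shape[0]
    r = cfg.missing_dwmri_region
    assert abs((n - dw_regions) / n - r) <= 3 * np.sqrt(r * (1 - r) / n)


def test_auc_recovery_matches_analytic_separation():
    # isolate the configured binormal/lognormal separation: no reader noise
    cfg = mapping_endometrial_like(seed=29, n_patients=667)
    cfg.reader_noise = {k: 0.0 for k in cfg.reader_noise}
    cfg.missing_dwmri_region = 0.0
    tables, _ = generate_cohort(cfg)
    df = build_region_table(join_regions(tables))
    for key, col, direction in [
        ("FDG_PET:suvmax", "fdg_suvmax", "greater_equal"),
        ("DWMRI:adc_mean", "adc_mean", "less_equal"),
    ]:
        sub = df[df[col].notna()]
        emp = roc_curve_auc(sub[col], sub["malignant"], direction).auc
        assert emp == pytest.approx(analytic_auc(cfg.markers[key]), abs=0.03)


def test_score_from_latent_extremes_and_monotonicity():
    vm = VisualModel()
    lo, hi = vm.thresholds[0], vm.thresholds[-1]
    assert score_from_latent(lo - 1.0, vm.thresholds)[0] == 1
    assert score_from_latent(hi + 1.0, vm.thresholds)[0] == 6
    u = np.linspace(lo - 2, hi + 2, 101)
    scores = score_from_latent(u, vm.thresholds)
    assert (np.diff(scores) >= 0).all()
    assert set(np.unique(scores)) <= set(range(1, 7))


def test_non_monotone_thresholds_rejected():
    with pytest.raises(ValueError, match="strictly increasing"):
        VisualModel(thresholds=(0.0, 1.0, 0.5, 2.0, 3.0))
    with pytest.raises(ValueError, match="strictly increasing"):
        score_from_latent([0.0], (1.0, 1.0, 2.0, 3.0, 4.0))


def test_visual_rule_matches_quadrature_oracle(rng):
    """Empirical sens/spec of the per-reader score>=5 rule vs numerical
    integration of the latent model (signal s + standard normal reader noise,
    positive iff u >= 4th threshold)."""
    vm = VisualModel()
    t5 = vm.thresholds[3]
    n = 5000
    d = rng.random(n) < 0.4
    z = rng.standard_normal(n)
    signal = vm.class_weight * d + vm.latent_weight * z
    scores = generate_visual_scores(signal, vm, rng)
    pos = scores >= 5

    def p_positive(class_shift):
        # integrate over the marker latent z; reader noise enters via Phi
        f = lambda zz: stats.norm.pdf(zz) * stats.norm.sf(
            t5 - vm.class_weight * class_shift - vm.latent_weight * zz
        )
        return integrate.quad(f, -8, 8)[0]

    sens_oracle = p_positive(1.0)
    spec_oracle = 1 - p_positive(0.0)
    assert pos[d].mean() == pytest.approx(sens_oracle, abs=0.03)
    assert (~pos[~d]).mean() == pytest.approx(spec_oracle, abs=0.03)


def test_reader_noise_for_icc_limits():
    assert reader_noise_for_icc(1.0, 0.5, "log") == 0.0
    # affine solves the classic variance-ratio identity
    sd = reader_noise_for_icc(0.6, 200.0, "affine")
    assert 0.6 == pytest.approx(200.0**2 / (200.0**2 + sd**2))
    with pytest.raises(ValueError):
        reader_noise_for_icc(0.0, 1.0)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="positive semi-definite"):
        SimulationConfig(latent_corr=np.array([[1, 0.9, 0.9], [0.9, 1, -0.9], [0.9, -0.9, 1]]))
    with pytest.raises(ValueError, match="scale"):
        MarkerParams(benign_loc=0, malignant_loc=1, scale=-1)
    with pytest.raises(ValueError, match="probability"):
        SimulationConfig(prevalence={"endometrial": 1.5})


def test_config_yaml_round_trip():
    cfg = mapping_endometrial_like(seed=99, n_patients=7)
    back = config_from_yaml(config_to_yaml(cfg))
    assert back.n_patients == cfg.n_patients
    assert back.markers == cfg.markers
    assert back.tumour == cfg.tumour
    assert np.allclose(back.latent_corr, cfg.latent_corr)
    assert back.seed == cfg.seed
    t1, _ = generate_cohort(cfg)
    t2, _ = generate_cohort(back)
    assert t1 == t2
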