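"""Cut-point optimisation, LOOCV, and the beta sweep."""

import numpy as np
import pytest

from nodalcut import (
    CutpointModel,
    CutpointSpec,
    beta_sweep,
    build_region_table,
    candidate_thresholds,
    classify_by_cutoff,
    generate_cohort,
    join_regions,
    loocv_predict,
    mapping_endometrial_like,
    optimal_cutpoint,
)


def brute_force_cutpoint(values, truths, direction, beta):
    """Independent exhaustive search with the documented tie-break."""
    best = None
    for c in sorted(set(values)):
        pred = [(v >= c) if direction == "greater_equal" else (v <= c) for v in values]
        tp = sum(p and t for p, t in zip(pred, truths))
        fp = sum(p and not t for p, t in zip(pred, truths))
        fn = sum((not p) and t for p, t in zip(pred, truths))
        tn = sum((not p) and (not t) for p, t in zip(pred, truths))
        if tp + fp == 0 or (tp == 0 and fn == 0):
            continue
        sens = tp / (tp + fn)
        ppv = tp / (tp + fp)
        if beta**2 * ppv + sens == 0:
            continue
        f = (1 + beta**2) * ppv * sens / (beta**2 * ppv + sens)
        spec = tn / (tn + fp) if tn + fp else float("nan")
        key = (round(f, 12), round(spec, 12), c if direction == "greater_equal" else -c)
        if best is None or key > best[0]:
            best = (key, c, f)
    return best[1], best[2]


def test_candidate_thresholds():
    assert list(candidate_thresholds([3, 1, 2, 2])) == [1, 2, 3]
    assert list(candidate_thresholds([5])) == [5]
    rng = np.random.default_rng(7)
    v = rng.normal(size=50)
    assert np.array_equal(candidate_thresholds(v), np.unique(v))
    with pytest.raises(ValueError):
        candidate_thresholds([])


def test_classify_by_cutoff_inclusive_directions():
    assert classify_by_cutoff(4.3, 4.3, "greater_equal") is True
    assert classify_by_cutoff(900.0, 847.0, "less_equal") is False
    assert classify_by_cutoff(846.9, 847.0, "less_equal") is True
    assert list(classify_by_cutoff([1.0, 2.0], 2.0, "greater_equal")) == [False, True]


def test_optimal_cutpoint_separable():
    values = [1, 2, 3, 4, 5]
    truths = [False, False, False, True, True]
    res = optimal_cutpoint(values, truths, CutpointSpec("m", "greater_equal", 1.0))
    assert res.cutoff == 4 and res.f_beta == 1.0
    assert (res.confusion.tp, res.confusion.fp) == (2, 0)


def test_optimal_cutpoint_less_equal_matches_exhaustive():
    values = [10.0, 20.0, 5.0, 15.0]
    truths = [False, False, True, True]
    res = optimal_cutpoint(values, truths, CutpointSpec("m", "less_equal", 1.0))
    oc, f = brute_force_cutpoint(values, truths, "less_equal", 1.0)
    assert res.cutoff == oc and res.f_beta == pytest.approx(f)


@pytest.mark.parametrize("direction", ["greater_equal", "less_equal"])
@pytest.mark.parametrize("beta", [0.5, 1.0, 2.0])
def test_optimizer_equals_brute_force_random(direction, beta, rng):
    for _ in range(25):
        n = int(rng.integers(6, 60))
        values = np.round(rng.normal(size=n), 2)
        truths = rng.random(n) < 0.35
        if not (truths.any() and (~truths).any()):
            continue
        res = optimal_cutpoint(values, truths, CutpointSpec("m", direction, beta))
        oc, f = brute_force_cutpoint(list(values), list(truths), direction, beta)
        assert res.f_beta == pytest.approx(f, abs=1e-12)
        assert res.cutoff == oc


def test_degenerate_all_equal_values():
    res = optimal_cutpoint([2.0] * 6, [True, False] * 3, CutpointSpec("m"))
    assert res.degenerate and res.cutoff == 2.0


def test_single_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        optimal_cutpoint([1.0, 2.0], [True, True], CutpointSpec("m"))


def test_duplicating_a_value_leaves_candidates_unchanged(rng):
    values = rng.normal(size=30)
    dup = np.append(values, values[4])
    assert np.array_equal(candidate_thresholds(values), candidate_thresholds(dup))


def test_loocv_separable_matches_full_fit():
    # boundary value duplicated so every fold retains the separating
    # candidate: leaving out a unique boundary record would necessarily
    # shift that fold's cut-off above the held-out value
    values = np.array([1, 2, 3, 10, 10, 11, 12], dtype=float)
    truths = np.array([0, 0, 0, 1, 1, 1, 1], dtype=bool)
    preds, median = loocv_predict(values, truths, CutpointSpec("m", "greater_equal", 1.0))
    assert all(p.prediction == t for p, t in zip(preds, truths))
    cutoffs = {p.fold_cutoff for p in preds}
    assert cutoffs == {10.0}
    full = optimal_cutpoint(values, truths, CutpointSpec("m", "greater_equal", 1.0))
    assert median == full.cutoff


def test_loocv_matches_hand_trace():
    """Five-record trace worked through fold by fold.

    Data (value, truth): (1,B) (2,B) (3,M) (4,B) (5,M), greater_equal, beta=1.
    Fold training optima: leaving out records 1,2,4,5 gives cutoff 3 (F of
    1/3, 0.8 or 1), leaving out the 3-M record gives cutoff 5; held-out
    classifications follow by the inclusive rule.
    """
    values = [1.0, 2.0, 3.0, 4.0, 5.0]
    truths = [False, False, True, False, True]
    preds, median = loocv_predict(values, truths, CutpointSpec("m", "greater_equal", 1.0))
    assert [p.prediction for p in preds] == [False, False, False, True, True]
    assert [p.fold_cutoff for p in preds] == [3.0, 3.0, 5.0, 3.0, 3.0]
    assert median == 3.0


def test_loocv_single_class_fold_gives_absent_prediction():
    values = [1.0, 2.0, 9.0]
    truths = [False, False, True]
    preds, _ = loocv_predict(values, truths, CutpointSpec("m"))
    assert len(preds) == 3
    assert preds[2].prediction is None  # leaving out the only malignant region
    assert preds[0].prediction is not None


def test_loocv_output_length_always_matches_input(rng):
    for _ in range(5):
        n = int(rng.integers(3, 40))
        values = rng.normal(size=n)
        truths = rng.random(n) < 0.3
        if not (truths.any() and (~truths).any()):
            continue
        preds, _ = loocv_predict(values, truths, CutpointSpec("m"))
        assert len(preds) == n


def test_beta_sweep_grid_of_one_reproduces_loocv(region_frame):
    sub = region_frame[region_frame["fdg_suvmax"].notna()]
    values = sub["fdg_suvmax"].to_numpy()
    truths = sub["malignant"].to_numpy(dtype=bool)
    spec = CutpointSpec("fdg_suvmax", "greater_equal", 1.0)
    table = beta_sweep(values, truths, spec, beta_grid=[1.0])
    preds, median = loocv_predict(values, truths, spec)
    assert len(table) == 1
    row = table.iloc[0]
    assert row["median_cutoff"] == median
    mask = [p.prediction is not None for p in preds]
    assert row["n"] == sum(mask)


def test_beta_sweep_requires_increasing_grid(region_frame):
    model = CutpointModel.from_dataframe(region_frame, "fdg_suvmax")
    with pytest.raises(ValueError, match="strictly increasing"):
        model.beta_sweep(beta_grid=[1.0, 0.5])


def test_cutoff_trajectories_move_with_beta_majority_of_replicates():
    """Raising beta favours sensitivity: SUV-like (greater_equal) median
    cut-offs should drift down and ADC-like (less_equal) cut-offs up, as a
    majority-of-replicates trend."""
    grid = [0.5, 1.0, 2.0]
    down, up, total = 0, 0, 0
    for seed in range(6):
        cfg = mapping_endometrial_like(seed=100 + seed)
        tables, _ = generate_cohort(cfg)
        df = build_region_table(join_regions(tables))
        ge = CutpointModel.from_dataframe(df, "fdg_suvmax").beta_sweep(grid)["median_cutoff"]
        le = CutpointModel.from_dataframe(df, "adc_mean").beta_sweep(grid)["median_cutoff"]
        down += ge.iloc[-1] <= ge.iloc[0]
        up += le.iloc[-1] >= le.iloc[0]
        total += 1
    assert down > total / 2
    assert up > total / 2


def test_model_from_dataframe_and_summary(region_frame):
    model = CutpointModel.from_dataframe(region_frame, "fdg_suvmax")
    assert model.direction == "greater_equal"
    assert model.nobs == region_frame["fdg_suvmax"].notna().sum()
    adc = CutpointModel.from_dataframe(region_frame, "adc_mean")
    assert adc.direction == "less_equal"
    cv = model.fit_loocv(bootstrap_B=100, seed=11)
    text = cv.summary()
    assert "median optimal cut-off" in text and "sensitivity" in text
    res = model.fit()
    assert res.f_beta == pytest.approx(
        max(res.f_beta, 0.0)
    ) and res.confusion.total == model.nobs
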