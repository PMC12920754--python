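# Methods

This note documents the statistical procedures `nodalcut` implements, the
synthetic data-generating model used to exercise them, the numerical choices
made where a convention had to be fixed, and the limits of what the test
suite can establish.

## Unit of analysis and data model

The analysis unit is the nodal region: one of three lymph-node basins (left
pelvic, right pelvic, para-aortic) per patient, labelled malignant when at
least one resected node from the basin is histologically malignant. Only
regions with corresponding histology enter any analysis; measurement or
visual rows without a histology match are dropped and counted. Cohorts are
stratified by cancer type (endometrial / cervical) before any testing.

ADC is stored and computed as the numeric value on the 10⁻⁶ mm²/s scale
(e.g. 847), which places the SUV-to-ADC ratio (STAR) near 5 × 10⁻³. Duplicate
measurement rows for the same (patient, region, modality, measure, reader)
are a hard error rather than being silently averaged: reader fusion is an
explicit, documented step and must not be pre-empted at parse time.

## Reader fusion and derived measures

Nodal fusion: mean of the two central readers when both measured; the single
central reading when only one did; the external third PET reader's value when
neither did. Primary-tumour fusion uses the central readers only (mean, or
the available one) — there is no external fallback for tumours.

NTR divides the fused nodal value by the fused primary-tumour value of the
same modality; STAR divides fused nodal SUV<sub>max</sub> by fused nodal
ADC<sub>mean</sub>. A derived value exists iff both operands exist; a
non-positive denominator yields an absent value with a logged reason. STAR
pairs SUV and ADC measured on the same *region* but not necessarily the same
physical node — no node matching is attempted, since readers of different
modalities work blinded to each other.

Visual positivity: a 6-point confidence score of 5–6 is malignant. How two
readers' scores combine into one region call is genuinely open; the default
is the most-suspicious-reader rule (positive iff max score ≥ 5), with
mean-then-round and single-reader policies selectable. The max rule was
chosen as the default because it mirrors clinical escalation (any reader
flagging a node triggers attention); the choice is recorded in the run log.

## Cut-point estimation and cross-validation

Candidate thresholds are the observed unique marker values, classified
inclusively (`≥ c`, or `≤ c` for ADC-based measures). The selected cut-off
maximises the training-set F<sub>β</sub> score,

    F_beta = (1 + beta^2) * PPV * sens / (beta^2 * PPV + sens),

whose reciprocal is the β-weighted mean of 1/sens and 1/PPV — which is why
the training sensitivity of the selected cut-off is non-decreasing in β (a
property the suite verifies on random data). Candidates where PPV and
sensitivity are both zero have undefined F<sub>β</sub> and are skipped.

Ties are broken deterministically: higher training specificity first, then
the largest cut-off for `≥` (smallest for `≤`) — conservative toward false
positives. Observed-value candidates were chosen over midpoints because the
analysis this package operationalises reports cut-offs that are plausibly
observed values, and the inclusive comparison is part of the procedure's
definition.

Out-of-sample performance uses leave-one-out cross-validation with the region
as the fold unit (leave-one-patient-out is a config option): each region is
classified by the cut-off fitted on all other regions, and the median fold
cut-off is the reported optimal cut-off. Folds whose training data collapse
to a single class yield an absent prediction with a warning. One structural
fact worth knowing: with observed-value candidates, "perfect" LOOCV recovery
on separable data (identical fold cut-offs, all held-out predictions correct)
holds only when the boundary value is shared by at least two records —
leaving out a unique boundary record necessarily shifts that fold's cut-off.

The β-sweep re-runs the full LOOCV pipeline over a grid (default
{0.25, 0.5, 1, 2, 4}) and tabulates median cut-off plus held-out metrics per
β.

## Comparison with visual assessment

Quantitative LOOCV predictions are paired with visual classifications by
(patient, region); both methods are evaluated on the identical paired set, so
reported N is the paired count, never the full cohort. McNemar's test uses
only the discordant counts b, c: exact two-sided binomial
(2·Binom(min(b,c); b+c, ½), capped at 1; p = 1 when b = c = 0) when
b + c < 25, else chi-square with continuity correction (|b−c|−1)²/(b+c). The
sensitivity test is restricted to truth-positive regions, the specificity
test to truth-negatives. All McNemar p-values of a cohort run (every measure
× {sensitivity, specificity}) form one Benjamini–Hochberg FDR family — the
family definition is a package choice, recorded in the run log, since no
single convention is canonical.

Confidence intervals are 95% percentile bootstrap with B = 1000 region-level
resamples and linear interpolation between order statistics; resamples where
a metric is undefined (empty denominator) are dropped with a logged count. A
patient-level cluster bootstrap is available by configuration because regions
within a patient are correlated; plain region resampling is the default.

## Supporting statistics

* Mann–Whitney U (two-sided) compares marker values between benign and
  malignant regions: exact enumeration when the smaller group has ≤ 8
  observations and no ties, otherwise the tie-corrected normal approximation.
  FDR adjustment across the measures of a cohort run.
* One-way ANOVA with Tukey HSD compares the three nodal regions per raw
  measure; a non-significant omnibus test pools regions downstream.
* Pairwise Pearson correlations use pairwise-complete observations with BH
  adjustment over the upper triangle; constant vectors are flagged undefined.
* ROC curves are empirical over all thresholds with trapezoidal AUC;
  `less_equal` markers are sign-flipped. AUC equals the tie-corrected
  Mann–Whitney U/(n₁n₂) (verified as a property test).
* Interobserver agreement is the one-way random-effects ICC(1) =
  (MSB − MSW)/(MSB + (k−1)·MSW) from the one-way ANOVA mean squares, with the
  F-distribution 95% CI. A one-way model has no consistency/absolute-
  agreement distinction, so a "one-way, consistency" specification resolves
  to ICC(1); note ICC(1) is invariant to global affine rescaling but *not* to
  per-subject or per-rater shifts (only two-way consistency ICCs are).
  Complete-case filtering drops subjects missing any reader, requiring ≥ 5
  complete subjects.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, so the pipeline is
testable end-to-end:

* One trivariate Gaussian latent per region (FDG-SUV, FEC-SUV, ADC) with
  correlation matrix defaulting to FDG–FEC = 0.80 and SUV–ADC = −0.25,
  reproducing strong cross-tracer correlation and weak inverse SUV–ADC
  coupling with few parameters. Class shifts the latent mean.
* Marginal transforms: exponential for SUV (log-normal, multiplicative reader
  error), affine truncated to positive for ADC.
* Reader noise is additive on the latent scale, independent across readers.
  Its SD is solved analytically from the target *observed-scale* ICC: for
  affine markers sd = scale·√((1−ICC)/ICC); for log-normal markers the
  moment decomposition of exp(latent + noise) gives
  s_w² = log1p((1 − e^(−s_b²))·(1 − ICC)/ICC). The pooled benign/malignant
  mixture adds between-region variance, so estimated ICCs sit slightly above
  the single-class target (≈ +0.01 at the default separation) — inside the
  ±0.05 recovery band the suite checks.
* Visual scores come from an ordinal-threshold model on
  u = a·d + b·z + e (d = true class, z = the marker latent, e = per-reader
  standard normal noise), binned by 5 increasing thresholds into scores 1–6.
  Defaults (a = 2.82, top threshold 2.10) were calibrated by numerical
  integration so the *combined* two-reader max rule sits near sensitivity
  0.84 / specificity 0.88 — better than the raw marker, as expert reads
  integrate morphology the markers do not carry.
* Primary-tumour values are drawn once per patient (location depending on
  nodal status) and shared across that patient's regions for NTR.
* Missingness: FEC PET absent for ~55% of patients (tracer logistics), DW-MRI
  absent for ~5% of regions, and each central PET reader independently omits
  a nodal reading with probability 0.10 (the external reader always records
  one), exercising every branch of the fusion rule.

Default study conditions (`mapping_endometrial_like`): 33 patients × 3
regions = 99 regions, region-level prevalence 31/99 ≈ 0.313, SUV class
separation set to AUC 0.85 (FDG) / 0.82 (FEC) on the latent scale, ADC
separation AUC 0.62 with malignant lower, reader ICC targets 0.95 (PET) and
0.60 (DW-MRI). Absolute class-conditional moments are not published for the
emulated study, so separations are anchored to its prevalence, AUC-like
discrimination, and reliability contrasts rather than to printed means.
`mapping_study_like` adds a small cervical cohort (12 patients, prevalence
0.12, reflecting that overtly node-positive cervical patients typically
bypass lymphadenectomy).

What the generator does **not** emulate: node-level substructure within
regions, FIGO-stage or histology effects on markers, scanner/protocol
heterogeneity, and correlated reader *bias* (noise is exchangeable across
readers). Passing tests therefore demonstrate correctness of the statistical
machinery under a plausible data-generating process, not clinical
conclusions about real cohorts.

## Determinism and problem sizes

Every stochastic step descends from one master seed through named substreams
(simulation / bootstrap), so re-running a configuration is byte-identical and
changing the bootstrap count does not perturb the simulated cohort. The test
suite's simulation sizes were chosen to make each check sharp but cheap:
optimizer-vs-oracle equality on 200 random datasets (n ≤ 60), threshold
recovery at n = 2000 across 20 seeds, ICC recovery over 200 replicates of
~100 regions, and bootstrap coverage over 500 replicates with B = 500.

## Known limitations

* The empirical F₁-maximising threshold is a noisy estimator when the F₁
  profile is flat near its optimum; at n = 2000 with unit-variance classes
  two SUV-scale units apart its sampling SD is ≈ 0.10, so individual
  replicates can land ~0.2 from the density-based optimum. Smoothed or
  midpoint estimators would reduce this but are deliberately out of scope.
* Percentile-bootstrap CIs can exclude the point estimate on degenerate
  resampling patterns; the results object attaches a warning rather than
  silently widening.
* With heavy missingness the paired N differs per measure; comparisons are
  valid within a measure's paired set but Ns are not comparable across
  measures.
* The cervical cohort at realistic size (36 regions, prevalence ~0.12) often
  lacks enough truth-positives for stable cut-points; the pipeline skips
  measures whose folds collapse to one class and logs the skip, mirroring the
  wide-CI caveat such cohorts warrant.
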