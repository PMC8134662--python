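# Methods

This note documents the models, the synthetic data generator, every
parameter that matters, and the design decisions taken where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The prediction framework

Three epsilon-SVR predictors of the 30-day NIHSS are compared on one shared
stratified 80/20 split:

* `M_CLINICAL`: SVR on RReliefF-selected clinical features
  (age, sex, baseline NIHSS, glucose, hematocrit, systolic blood pressure,
  atrial fibrillation, hypertension, hyperlipidemia, treatment indicator,
  onset-to-admission time).
* `M_RELIEF` / `M_LSM`: nested models
  `NIHSS_30d ~ clinical + (NIHSS_48h ~ imaging)`. The inner SVR maps
  region-level imaging features to the 48-hour NIHSS; its prediction is one
  extra column of the outer SVR. The arms differ only in how imaging
  regions are selected (RReliefF vs lesion-symptom mapping), always against
  the **48-hour** score and always on training rows only.

SVR defaults (unstated in the source analysis, so fixed here): RBF kernel,
C = 1, epsilon = 0.1, gamma = 1/(d·Var) (`scale`), features standardized
with training-set mean/SD inside the pipeline. Constant feature columns are
dropped with a warning. 30-day predictions are clamped to [0, 42] but not
rounded.

**Out-of-fold inner predictions.** Whether the original inner model's
training-time predictions were in-sample is unknown. In-sample stacking is
optimistic — the outer model would calibrate against inner predictions of
unrealistically high quality — so the inner predictions fed to outer
training are 5-fold out-of-fold within the training set (`oof=False`
restores in-sample stacking).

**Stratified split.** Strata are quartiles of the 30-day NIHSS ("stroke
severity" made concrete); bins with fewer than 2 patients merge into a
neighbour with a warning. The global test count is round(0.2·n); exact
per-stratum quotas are rounded by largest remainder so the global count is
hit exactly (221 patients → 44 test). Sampling within strata is seeded and
reproducible.

## Lesion-symptom mapping

At every voxel lesioned in ≥10% of patients (inclusive threshold — "at
least") with at least 2 patients in each of the lesioned/intact groups, the
Brunner–Munzel statistic compares the groups' 48-hour scores using
mid-ranks:

    Si² = 1/(ni−1) Σk (Rik − R(i)ik − R̄i + (ni+1)/2)²
    W   = n1 n2 (R̄2 − R̄1) / ((n1+n2) √(n1S1² + n2S2²))
    df  = (n1S1² + n2S2²)² / ((n1S1²)²/(n1−1) + (n2S2²)²/(n2−1))

with a two-sided p from the t distribution (sidedness is a choice: after
ranking, deficits could associate in either direction). The map is
evaluated for all voxels at once by collapsing patients onto distinct score
values; per-voxel group rank structure then reduces to per-value lesion
counts obtained from one matrix product, which is what makes the
permutation studies cheap.

* **FDR**: Benjamini–Hochberg step-up (the default in the LSM package
  ecosystem), via statsmodels. Voxels with zero pooled rank variance
  (e.g. complete separation) are flagged degenerate, assigned the
  conservative p = q = 1, and excluded from the FDR pool — treating them
  as findings would inflate the map.
* **Weights and ROIs**: surviving voxels (q ≤ 0.05) get weight |W|; only
  the nonzero/zero distinction matters downstream — every atlas region
  containing ≥1 nonzero-weight voxel becomes an ROI.

## RReliefF

Regression Relief with m sampled instances and k nearest neighbours
(Manhattan distance on min–max-normalized features; target difference
normalized the same way; neighbour influence uniform 1/k; distance ties
broken by lowest instance index; zero-range features have diff 0):

    W[A] = N_dC&dA[A]/N_dC − (N_dA[A] − N_dC&dA[A])/(m − N_dC)

which is always in [−1, 1]. `m=None` runs a deterministic exhaustive pass.
The canonical exponential rank-decay neighbour weighting is deliberately
replaced by the uniform 1/k (common package default, and it keeps the
brute-force oracle trivial); the selection rule keeps strictly positive
weights, giving a data-determined feature count. A region is retained when
any of its 1–3 feature columns is selected.

**Sample size.** The historical default m = 10, k = 5 is kept on
`rrelieff` and the `select-features` CLI. The experiment driver, however,
defaults to the exhaustive pass: with only a few dozen feature columns
(against hundreds in a full-scale parcellation), the m = 10 estimate's
sign noise makes region selection erratic, and that sampling variance is a
property of the estimator, not of the two selection strategies the
experiment compares. Set `ExperimentConfig(relieff_m=10)` for strict
historical parameters.

## Imaging features

* `gm_overlap` / `wm_overlap`: relative lesion overlap
  |lesion ∩ region| / |region|.
* `wm_integrity`: spared cross-section of a WM tract, the **minimum** over
  slices along the tract's declared axis of 1 − |lesion ∩ tract ∩ slice| /
  |tract ∩ slice|. Minimum rather than mean because a single full
  transection disconnects a tract (`mode="mean"` is available).
  "Cross-sectional width" is operationalized as a voxel-count fraction,
  which is robust on coarse grids.

## The synthetic cohort generator

The generator emulates the statistical structure of a pooled acute-stroke
trial cohort; it makes no attempt at anatomical realism beyond what the
pipeline is sensitive to (spatially coherent lesions, a vulnerable
territory, parcels of both tissue classes).

* **Atlas**: 32³ grid, 1 mm isotropic, identity affine; brain = inscribed
  ellipsoid (~17k voxels). Default 24 GM spherical parcels (radius 2–3.5)
  and 6 axis-aligned WM bars, packed disjointly with seeded rejection
  sampling; 8 GM parcels are forced inside the lesion territory because a
  whole-brain parcellation always has parcels inside a vascular territory,
  and the density matters — Relief needs enough feature columns for
  neighbour distances to be informative.
* **Lesions**: the target voxel count is uniform on (100, 1500); the lesion
  is exactly that many voxels nearest a centre under a per-axis stretched
  metric (jittered ellipsoids), clipped to the brain. Centres fall inside
  an MCA-like territory (ball of radius 9 at an off-centre, lateralized
  position) with probability 0.8, else uniformly in the brain. These sizes
  make the territory core lesioned in a large share of patients, matching
  the high lesion-overlap core of real MCA cohorts; smaller/sparser lesions
  would leave almost no voxel past the 10% coverage filter.
* **Outcomes** (integers, clipped to [0, 42]):

      NIHSS_48h = a1·NIHSS_base + Σr βr·overlap_r + Σt γt·(1−integrity_t) + ε1
      NIHSS_30d = d0 + d48·NIHSS_48h + Σc δc·z(covariate_c) + ε2

  with a1 = 0.85, ε1 ~ N(0, 3), d48 = 0.85, ε2 ~ N(0, 2.5), and fixed
  population standardization z(·) for continuous covariates. Default
  eloquent effects: β = 10/9/8 NIHSS points per unit overlap on the three
  GM parcels nearest the territory centre (eloquence belongs to the
  vulnerable territory, as in real MCA anatomy), γ = 6 on the nearest WM
  tract. The ground-truth JSON lists exactly the regions with positive
  effects.
* **Covariates**: plausibility-anchored marginals, not calibrated fits —
  age ~ N(69, 14) truncated [30, 95], baseline NIHSS ~ round N(15, 6)
  clipped [2, 30] (anchored to published cohort medians/IQRs), binary risk
  factors Bernoulli with configurable prevalences, onset-to-admission
  log-normal around 152 min.
* **Determinism**: one seed per cohort; per-patient substreams derived via
  `SeedSequence([seed, i])`, so enlarging the cohort never reshuffles
  earlier patients. On-disk output (uncompressed-payload `.nii.gz`, CSV,
  JSON) is byte-identical across runs.

**What passing tests do and do not show.** The generator's outcome chain is
exactly the linear-plus-noise structure the nested model assumes, lesions
are clean binary masks in perfect registration, and covariates are
independent of lesion topography. Success here demonstrates that the
machinery — selection, nesting, leakage control, statistics — behaves
correctly and that the comparison is implemented fairly; it says nothing
about predictive accuracy on real stroke data, where registration error,
atlas mismatch, non-linear deficits and correlated covariates all bite.

## Numerical and procedural choices

* Coverage threshold inclusive (≥ 10%), applied at voxel level for LSM and
  region level ("any lesioned voxel") before Relief.
* Degenerate Relief edge cases: constant target is an error; N_dC = 0
  zeroes the concordant term; m = N_dC zeroes the discordant term.
* Empty selected ROI set: the inner model degenerates to the training-mean
  predictor with a warning, making the nested arm collapse onto the
  clinical baseline rather than fail.
* `model_pvalue` (the per-model p) is the two-sided test of zero linear
  association between predicted and observed test scores — an
  interpretation, stated as such. MAE differences use the two-sided paired
  Wilcoxon signed-rank on per-patient absolute errors (NIHSS errors are
  non-normal, test sets small); all-zero differences give p = 1.
* Test-set R² is 1 − SSres/SStot (may be negative), not squared
  correlation.

## Problem sizes

Simulation studies in the tests and the acceptance script use n = 200
cohorts for the LSM calibration/recovery studies (100 permutations,
20 cohorts), n = 400 for the 20-cohort model-comparison study, and n = 221
— the design cohort size — for the single worked analysis. These sizes give
stable Monte-Carlo rates while keeping any single study in the
tens-of-seconds range.

## Known limitations

* Single-pass Relief selection; the historical "iterative" procedure is
  not elaborated anywhere and is not implemented.
* The tract-integrity operator (minimum spared cross-section) is one
  defensible reading of "cross-sectional width of the tract spared";
  per-slice mean is available but geometric width is not.
* No probabilistic atlases, no registration or segmentation, no
  bilateral-lesion exclusion logic: synthetic data are generated already
  clean.
* No ordinal-regression variant; predictions are continuous and clamped.
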