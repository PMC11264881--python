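# Methods

`neometab` implements a metabolome-wide association workflow for untargeted
neonatal dried-blood-spot (DBS) metabolomics in a matched case-control
design, together with the downstream analyses such a study needs: QC-based
drift correction, missingness-stratified feature modeling, covariate-adjusted
logistic association with FDR control, metabolite-class enrichment,
partial-correlation networks, MS/MS library annotation, and a genetic and
dietary determinant scan in an adult cohort. Because individual-level
neonatal screening data cannot be redistributed, the package ships a
first-class synthetic-cohort generator that reproduces the statistical
structure the analysis assumes, with ground truth for recovery testing.

## Study design emulated by the generator

The neonatal cohort is a 1:1 matched case-control sample of male newborns.
Matching calipers are birth date within 14 days, gestational age within 4
days and age at heel-prick sampling within 1 day; gestational age lies in
weeks 34-42 and sampling age in days 3-8. Season of birth follows the
calendar rule (December-February is winter, and so on by three-month
blocks). Confounders:

* family history of psychiatric disorders ~ Bernoulli(0.300) in cases and
  Bernoulli(0.187) in controls (the observed cohort proportions, 222/739 and
  138/739);
* a standardized polygenic score drawn from the binormal model: unit normal
  in controls, shifted by `delta = sqrt(2) * Phi^-1(AUC)` in cases, with
  AUC = 0.58 by default;
* six genetic principal components, independent unit normals;
* age at diagnosis for cases ~ Normal(6, 2) truncated to [1, 10] years
  (mean diagnosis age 6.0; diagnosis before the 10th birthday).

### Feature matrix

Feature intensities are log-normal. Per feature `f`: location
`mu_f ~ Normal(ln 1e5, 1)`; between-subject (biological) log-scale SD 0.35;
technical (analytical) log-scale SD `analytical_cv = 0.03`. The technical SD
is what repeated injections of a pooled QC sample show after drift removal;
3% is a realistic repeatability for abundant features on a well-behaved
LC-MS platform and is exposed in the configuration. Structure added on top:

* **Plate batches.** Samples are randomized over plates (19 by default);
  each plate gets a log-scale offset ~ Normal(0, `batch_sd`), default 0.1.
* **Injection-order drift.** Multiplicative
  `g(order) = 1 + A * sin(pi * order / (2 L) + phi_p)` with plate length
  `L`, relative amplitude `A = drift_amplitude` and a random per-plate phase
  `phi_p`. Within one plate the curve is smooth and slowly varying (a
  quarter sine cycle), which is what a locally weighted correction assumes;
  across plates the random phase makes batches sit at different levels, so a
  run with `A = 0.5` shows pooled QC RSDs of 25-40% before correction. A
  phase-free single-arch sine was considered and rejected: its pooled
  relative spread is far too small to emulate a run that visibly needs
  correction.
* **Left-censored missingness.** Each feature has a target detection
  fraction; its detection limit is set at the corresponding quantile of the
  feature's base log intensity, so missingness is intensity-dependent
  (left-censoring), as in real peak detection. Default targets are drawn to
  reproduce the observed post-filter composition (452 of 865 retained
  features continuous, 413 binary) plus a 5% fully-censored tail, with
  targets kept away from the 25%/75% boundaries so the realized stratum is
  stable under sampling noise.
* **QC rows.** Each plate carries 10 pool injections (used to fit the drift
  curve) and 2 external-control injections, evenly spaced over the plate,
  with technical noise only plus the same plate offset and drift.

### Planted effects

Continuous effects are planted retrospectively: the feature is drawn
conditional on case status with an equal-variance Gaussian shift on the log
scale, which by Bayes' rule induces a logistic model in case status. The
shift `d` is calibrated so that the odds ratio per *pooled* standard
deviation equals the requested value: `d * sqrt(1 + d^2/4) = ln(OR)`
(`synthetic_data.shift_for_or`). This matters because the association stage
standardizes features over all analytical samples; planting `d = ln(OR)`
directly would overstate the per-SD effect by the pooled-SD inflation
`sqrt(1 + d^2/4)` and bias coverage tests. Binary effects are planted on the
presence indicator: per-group presence probabilities are solved so that the
overall detection fraction hits the feature's target and the presence odds
ratio equals the requested value. For binary signal features presence is
drawn directly per group rather than through the censoring quantile; the
intensity values of present cells are ordinary log-normal draws, so the
intensity-presence coupling is not preserved for those features (only the
mask carries the signal, which is all the binary analysis uses).

### Adult cohort

Genotypes are Hardy-Weinberg with MAF ~ Uniform(0.05, 0.5). The metabolite
is a linear model in causal dosages plus standardized (log-scale) dairy
intake plus Gaussian noise; each causal SNP's coefficient is scaled to
explain its stated variance fraction, and the dairy coefficient is set via
the Gaussian-copula relation `rho_S = (6/pi) asin(rho/2)` so the partial
Spearman correlation hits its target (0.18 by default). Covariates: age,
sex, BMI, non-alcoholic energy intake; six energy-adjustable dietary intake
groups.

## Drift correction (QC-RLSC)

For each plate and feature a locally weighted curve is fitted to the QC pool
intensities versus injection order: tricube weights over the span-nearest
fraction of QC points (span 2/3 by default), local polynomial of degree 1
("low-order"; degree 2 available). Fewer than 4 usable QC points means the
feature is passed through uncorrected and logged. Analytical samples are
corrected as `raw * reference / f(order)`; evaluation is clamped to the
observed QC order range to avoid extrapolating the local polynomial.

The reference constant is the run-wide per-feature QC median, not the
per-plate median. With per-plate curves a per-plate reference would leave
each plate parked at its own drift level (the cross-plate QC RSD stays at
~25% in simulations); a single reference puts all plates on a common scale
and is what makes the corrected QC RSD collapse to the technical CV.
`fit_drift_curve` used standalone keeps the median of the QC values it was
given as its reference.

Per-plate fitting is the default (QC pools are plate-specific); a global
mode fitting one curve across the run is available.

## Feature triage and coding

Presence fractions are computed over analytical samples only. Features
detected in less than 25% of samples are dropped; in less than 75%, coded as
binary present/absent (a measured zero counts as present); otherwise
continuous. Boundaries are literal: exactly 0.25 is binary, exactly 0.75 is
continuous. Continuous features are imputed (iterative depth-limited
regression trees on the log scale, half-minimum initialization; a plain
half-minimum mode is available), batch-corrected (per-plate median alignment
of log intensities), then natural-log transformed and standardized to mean 0
and SD 1 (ddof = 1) over all analytical samples, cases and controls
together. The standardization population and log choice are recorded in the
output metadata, since per-SD odds ratios depend on them. The stage order is
fixed: impute, then batch-correct, then standardize.

Quartile coding is rank-based over the full analytical cohort, ties by
average rank with boundary ranks assigned to the lower bin, Q1 the reference
category.

## Association models

Unconditional maximum-likelihood logistic regression adjusted for the
matching factors; the pair identifier is ignored (conditional logistic is a
non-goal). Model 1 adjusts for gestational age, age at sampling, season of
birth (three dummies, winter reference) and birth year; model 2 adds family
history, the polygenic score and six principal components. Continuous
covariates are mean-centered for conditioning; this does not change feature
coefficients. Wald 95% CIs and p-values are reported. Complete or
quasi-complete separation (judged on the feature coefficient) triggers a
ridge-penalized logistic fallback (alpha = 0.5 on non-intercept terms, Wald
quantities from the penalized Hessian), flagged `penalized`. Failed fits
enter the BH adjustment with p = 1 rather than shrinking the number of
tests. FDR control is Benjamini-Hochberg across all tested features
jointly.

The age-of-diagnosis stratified analysis fits each stratum's cases against
the full shared control group (flagged in the output). Effect heterogeneity
is tested case-only: a logistic model of early-versus-late diagnosis among
cases on the feature plus covariates; the feature's Wald test equals the
feature-by-stratum product-term test in the polytomous augmentation. This
was an open design point; the case-only form was chosen because it needs no
duplicated control rows and is the standard heterogeneity test for case
subtypes with shared controls.

Cohort-table statistics: pooled-variance two-sided t-test (Welch available)
and Pearson chi-square without continuity correction. Single-marker
discrimination is the rank-based (Mann-Whitney) AUC with ties counted 0.5.

## Enrichment and networks

Class enrichment is the classical two-sided Fisher exact test (all tables
with point probability at most the observed) on significant-by-class 2x2
tables over annotated features. Feature-feature partial correlations
"adjusted for all other features" come from the standardized inverse
correlation matrix, `rho_ij = -Omega_ij / sqrt(Omega_ii Omega_jj)` —
algebraically identical to residualizing every pair on all other columns but
one matrix inversion instead of thousands of regressions; p-values use the t
transform with df = n - p. Exact mode requires n > p; a flagged
ridge-regularized mode (`R + lambda I`) covers the near-degenerate case
(865 features, 1478 samples leaves df small — both modes are provided and
neither is asserted as the original analysis). Binary presence indicators
enter as 0/1 numeric.

Partial Spearman correlations rank-transform all variables (covariates
included, as the reference R implementation does), residualize the two ranks
of interest on the covariate ranks and correlate the residuals, df =
n - k - 2. Dietary intakes are energy-adjusted by dividing with
non-alcoholic energy intake.

## Spectral matching

Plain cosine over tolerance-matched fragment pairs (no precursor-shifted
"modified cosine"), raw intensity weighting by default with a square-root
toggle. Pairing is greedy by descending intensity product, ties by smaller
m/z difference, each peak used once — deterministic, and on random spectra
with up to 6 peaks it agrees with the exhaustive optimal assignment to
1e-9 (and with the community implementation in matchms to machine
precision). A library hit requires all of: parent mass difference strictly
below 0.05 Da, cosine strictly above 0.7, and at least 4 matched peaks. The
normalization uses all peaks of both spectra, so a spectrum's self-cosine is
exactly 1.0.

## Genetic and dietary determinant scan

The GWAS is ordinary least squares of the metabolite on additive dosage
(0/1/2) plus covariates per SNP, vectorized by projecting the covariates out
of the phenotype and the dosage matrix once (Frisch-Waugh-Lovell), which is
exactly the per-SNP multiple regression. Monomorphic SNPs get NA estimates
and a flag. Genomic control lambda is median chi-square over 0.4549.

The phenome-wide scan is LASSO over a standardized mixed predictor table;
the penalty path runs log-spaced from the critical penalty that zeroes all
coefficients down three decades, and the penalty is chosen by k-fold (10)
cross-validated prediction error with the one-standard-error rule. Reported:
nonzero coefficients ranked by magnitude and the out-of-fold R² at the
chosen penalty.

## Numerical and testing notes

* Seeds: a single pipeline seed is expanded with a counter-based
  `SeedSequence([seed, stage])` scheme, so toggling one stage never
  reshuffles another's randomness. Identical configuration and seed give
  byte-identical output files.
* Problem sizes in the test suite and acceptance script: calibration uses
  100-pair, 800-feature null cohorts (50 replicates in the tests, 10 in the
  acceptance script); effect recovery uses the full 739-pair design with a
  small feature panel; GWAS power uses n = 3409 with a 30-SNP panel and
  calibration a 5000-SNP null panel. These sizes keep the full suite within
  minutes while leaving the Monte-Carlo bands far narrower than the margins
  being checked.
* What the synthetic data does *not* emulate: correlated feature blocks
  (features are independent given case status), retention-time structure,
  isotope/adduct redundancy, registry-based outcome misclassification,
  storage-time decay, and intensity-presence coupling for binary signal
  features. Passing recovery tests therefore demonstrates correctness of
  the estimators under the generative model, not robustness to those
  real-data phenomena.
* Known limitations: the ridge partial-correlation mode trades bias for
  existence and its p-values are approximate; the penalized logistic
  fallback gives shrunken estimates near separation; the tree imputer is a
  documented lightweight stand-in for forest-based imputation.
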