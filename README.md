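# neometab

Metabolome-wide association analysis for untargeted neonatal dried-blood-spot
(DBS) metabolomics in a matched case-control design — the setting of
newborn-screening biobank studies where heel-prick spots collected days 3-8
after birth are profiled years before a clinical diagnosis is made.

The package implements the full analysis chain such a study needs, plus a
synthetic-cohort generator (individual-level screening data cannot be
redistributed, so all analyses are exercised end-to-end on simulated cohorts
with known ground truth):

* **QC-RLSC drift correction** — per plate and feature, a LOESS curve
  f(order) (tricube weights, span α = 2/3, local degree 1) is fitted to
  repeated QC-pool injections versus injection order and analytical samples
  are normalized as x · ref / f(order).
* **Missingness-stratified feature modeling** — features detected in < 25%
  of samples are dropped, in < 75% coded binary (present/absent), otherwise
  imputed, batch-corrected, log-transformed and standardized.
* **Association scan** — per feature, unconditional logistic regression of
  case status adjusted for the matching factors (gestational age, age at
  sampling, season of birth, birth year; a second model adds family history,
  a polygenic score and six genetic PCs). Odds ratios are per SD for
  continuous features (OR = e^β with x standardized) and per presence for
  binary features, with Wald 95% CIs and Benjamini–Hochberg q-values across
  all features jointly; quartile coding and age-at-diagnosis
  stratified/interaction analyses for top hits.
* **Enrichment and networks** — two-sided Fisher exact metabolite-class
  enrichment; partial Pearson correlations between features from the inverse
  correlation matrix (ρ_ij = −Ω_ij/√(Ω_ii Ω_jj)); partial Spearman
  correlations of metabolites with energy-adjusted dietary intakes.
* **MS/MS annotation** — MASST-style library search: spectral cosine over
  tolerance-matched peaks, accepted at cosine > 0.7, ≥ 4 matched peaks,
  parent mass difference < 0.05 Da.
* **Determinant scan** — per-SNP additive linear GWAS (β, SE, Wald p, λ_GC
  diagnostics) and a LASSO phenome-wide scan with cross-validated penalty
  (one-standard-error rule).

See `docs/methods.md` for the model details and design choices.

## Worked example

Run the bundled demo pipeline (200 matched pairs, 100 features, two planted
effects — a continuous feature at OR 2.0 per SD and a binary feature at
presence OR 3.0):

```bash
neometab run --seed 5 --out runs/demo
```

The run directory contains the raw and drift-corrected feature tables, the
stratum assignments, the association table `assoc.tsv` and a
`manifest.json` recording every software decision (LOESS span, imputation
method, FDR procedure, per-stage seeds). The top of `assoc.tsv` sorted by
q-value:

```
feature_id  mode               estimate  ci_low  ci_high  p         q
F0001       continuous_per_sd  1.585     1.284   1.956    1.8e-05   8.7e-04
F0002       binary_presence    2.658     1.715   4.118    1.2e-05   8.7e-04
F0005       binary_presence    0.526     0.351   0.786    1.7e-03   5.5e-02
```

The two planted features are the only q < 0.05 discoveries, with estimates
near their true values (1.59 for the planted OR 2.0 per SD — this seed drew
a low realization; 2.66 for the planted presence OR 3.0); the strongest
null feature (F0005) stops at q = 0.055. The
manifest reports the mean QC RSD falling from 12.7% to 2.4% after drift
correction.

Every stage is also a library call (`neometab.association.run_mwas`,
`neometab.qc_normalization.fit_drift_model`, ...) and a CLI subcommand
(`simulate`, `normalize`, `process`, `mwas`, `enrich`, `pcorr`, `specmatch`,
`gwas`, `phewas`).

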