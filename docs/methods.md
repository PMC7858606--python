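# Methods

This package re-implements, as a tested pipeline over synthetic data, a
complete analysis of technical versus biological variation in label-free
DIA (SWATH-type) proteomics of CLL patient samples: preprocessing,
variance decomposition, batch correction with retention assessment,
partial-correlation signatures, gene set enrichment, and an
abundance-dependent error model that yields proteome-wide statistical
power and sample-size tables.

## Study design and the synthetic generator

The design being emulated is 6 patients (3 with unmutated IGHV, UM-CLL;
3 mutated, M-CLL), each prepared for MS on 3 separate days, each
preparation acquired 3 times — 54 acquisitions.  The generator
(`synthdata`) draws, per protein *g* and acquisition *s* (patient *p*,
prep day *d*, run *r*):

```
log2 y[g,s] = base_g                      # N(15, 3^2) log2 units
            + (fc_g / 2) * group_sign(p)  # ±de_log2fc/2, UM vs M
            + patient[g,p]                # N(0, patient_sd^2)
            + day_shift[d] + jitter[g,d]  # additive prep-day batch
            + prep[g,p,d]                 # per-preparation block noise
            + scale_d * sigma_g * z       # measurement noise
            + run noise                   # N(0, run_noise_sd^2)
```

with raw intensity `2**log2 y` and logistic, abundance-dependent dropout
capped at `missing_max_rate`.

* **CV curve.** `sigma_g` is set from the injected CV-vs-abundance curve
  `CV(x) = cv_floor + cv_amplitude * exp(-cv_decay (x - ref_log2))`
  (defaults 5% floor, 60% amplitude, 0.5 per log2 unit, anchored at
  log2 abundance 8) through the log-normal identity
  `sigma_log2 = sqrt(ln(1 + (CV/100)^2)) / ln 2`.  The curve therefore
  governs the *per-acquisition* replicate noise; patient and preparation
  effects add on top, which is why the CV measured across all 54
  acquisitions of a default study sits above the injected floor.
* **Batch model.** The prep-day effect is a day-level location shift
  plus per-protein jitter (both N(0, 0.5^2) log2 by default) and an
  optional per-day multiplicative inflation of the measurement-noise SD
  — exactly the location/scale structure the empirical-Bayes correction
  assumes.
* **Block noise.** `prep_noise_sd` (default 0.1 log2) is drawn once per
  (protein, patient, prep-day) and shared by that preparation's MS runs.
  It is the mechanism that makes technical replicates within a block
  correlated, which the batch-in-model variant estimates and absorbs.
* **Clinical covariates.** M-CLL patients draw %-IGHV uniformly on
  (2.1, 15), UM-CLL on (0, 1) — straddling the 2% diagnostic cutoff as
  in the cohort being emulated (observed range 0–14%).  The first
  patient of each group is female and the last has a high WBC; these
  fixed patterns keep IGHV status, WBC class and gender mutually
  non-aliased in a 6-patient joint model.
* **Missingness.** Dropout probability is
  `missing_max_rate * logistic(-(base_g - midpoint)/width)` — monotone
  decreasing in abundance, with the midpoint defaulting to the 10th
  percentile of base abundances.  No quantitative description of the
  real missing-data pattern exists, so this is a plausible stand-in and
  is documented as such.
* **Seeding.** One master seed spawns independent sub-streams per stage
  (abundances, fold changes, patient effects, batch, noise, dropout,
  roster), so generation is bit-reproducible and changing one parameter
  perturbs only its own stream.

What passing tests on this generator do *not* show: real SWATH data have
peptide-level structure, correlated missingness, non-Gaussian tails and
shared-peptide quantification artefacts that the log-normal model omits.
The tests establish that the statistical machinery is correct under its
own assumptions, not that those assumptions exhaust real data.

## Preprocessing

Fixed order: total-area normalisation (each acquisition scaled so its
observed sum equals the mean of the original column sums) → log2 →
low-background filter → imputation → accession-to-gene collapse.

* The low-background rule is operationalised as: drop proteins whose
  median intensity falls strictly below the 2% quantile of all protein
  medians (the rule is monotone-invariant, so raw or log2 input gives
  identical results).  The default drops ~1–2% of proteins, matching
  the magnitude of the reduction in the workflow being reproduced
  (5179 → 5108, 1.4%); the exact original rule is not recoverable and
  no claim of identity is made.
* Gene collapse keeps, per gene symbol, the single accession row with
  the highest mean observed intensity; no values are invented.
* Imputation is iterative tree-ensemble regression (extremely
  randomised trees behind scikit-learn's iterative imputer): each
  protein with missing entries is regressed across acquisitions on the
  50 most-correlated other proteins, cycled up to 10 rounds, fixed
  seed.  Observed entries are never altered.  The algorithm family
  (random-forest-style iterative imputation) is specified; tree count,
  predictor restriction and iteration cap are this package's choices,
  selected for determinism and tractable runtime at proteome scale.

## Per-protein inference

* **ANOVA.** One additive fixed-effects model per protein with all five
  factors (IGHV status, WBC class, gender, prep day, MS run); per-factor
  F tests use Type II sums of squares (drop the factor from the full
  model); BH step-up FDR per factor across proteins; significance at
  q ≤ 0.10.  All 54 acquisitions enter as replicates — deliberately
  reproducing the analysed design, which treats technical replicates as
  biological ones and therefore overstates evidence for patient-level
  factors; the batch-in-model variant is the principled counterpoint.
  Verified against statsmodels `anova_lm(typ=2)`.
* **Moderated fit.** Per-protein OLS for a two-level contrast, residual
  variances shrunk by moment-matching the log-variance distribution
  (digamma/trigamma inversion for the prior df `d0` and prior scale
  `s0^2`), moderated t on `df + d0` degrees of freedom.  Matches the
  limma reference (`lmFit` + `eBayes`) to machine precision on shared
  inputs; a single-protein input carries no shrinkage information and
  falls back to the ordinary t.
* **Partial correlation.** Pearson correlation of residuals after
  least-squares removal of binary-coded WBC and gender;
  `t = r sqrt((n-2-k)/(1-r^2))` on `n-2-k` df.  The confounder basis is
  rank-revealing, so redundant confounders are tolerated; a protein
  fully explained by the confounders gets r = 0 and p = NaN.
* **PCA.** Protein-centred SVD; component variances sum to the total
  protein-wise variance; sign fixed by making the largest-magnitude
  loading of each component positive.
* Proteins with zero residual variance get NaN p-values and are
  excluded from BH with the q-values of the rest unaffected.

## Batch correction

* **Empirical-Bayes location/scale (`eb_batch_correct`).** The
  parametric ComBat algorithm, re-implemented: fit batch indicators plus
  (supervised) protected covariates per protein; standardise by the
  pooled residual SD; estimate per-batch per-protein locations and
  scales on standardised data; shrink via normal / inverse-gamma priors
  with method-of-moments hyperparameters and fixed-point iteration
  (tolerance 1e-4, max 100); remove shrunken effects and restore grand
  mean and covariate effects untouched.  Only the parametric prior is
  implemented (the cited method's default); supervised mode protects
  IGHV status, WBC class and gender.  The sva implementation serves as
  a test oracle (agreement to ~1e-8), never as the implementation.
* **Regression removal (`regression_batch_remove`).** Per-protein least
  squares with sum-to-zero batch coding; only the fitted batch
  component is subtracted.
* **Batch-in-model (`batch_in_model_fit`).** The moderated fit with
  prep day as a fixed covariate, plus generalised least squares:
  technical replicates within a (patient, prep-day) block are given a
  common correlation ρ̂ and whitened by the inverse square root of the
  compound-symmetry block correlation.  ρ̂ is a pooled method-of-moments
  ratio of within-block pairwise covariance to residual variance,
  computed on residuals of a technical-effects-only fit (intercept +
  prep day): with only 6 patients, including patient-level covariates
  in the residualisation would absorb much of the block-shared variance
  and bias ρ̂ downward.  This is a documented approximation of the
  consensus-correlation procedure, not a reproduction of its REML
  internals.
* **Comparison harness.** Per-factor significant counts for the
  uncorrected data and each method, retention of the IGHV-significant
  set, and pairwise overlaps.  Retention is measured like-for-like:
  matrix-level methods against the uncorrected ANOVA set, the
  batch-in-model variant against the uncorrected moderated fit.

## Error model and power

* Per-protein CVs are computed on raw-scale intensities; the default
  replicate set is *all* acquisitions pooled (the analysed design's
  convention), with within-patient and within-group alternatives.  The
  default pipeline computes CVs on batch-corrected data back-transformed
  from log2 — power analysis follows correction in the workflow — and a
  pre-correction option exists.  Whether CVs should be computed on raw
  or log2 intensities is not externally fixed; the raw-CV-to-log2-sigma
  conversion used here is validated by simulation (round-trip through
  log-normal data recovers the CV).
* The CV-vs-abundance curve is a hand-rolled loess: at each of 200
  evenly spaced grid points, tricube weights over the span-nearest
  neighbours and a weighted degree-1 (or 2) polynomial; no robustness
  iterations; predictions floored at 0.1% CV and clamped beyond the
  grid.  Default span 0.75 (display-style smoothing); the consistency
  experiment uses span 0.1, appropriate for estimating a steep
  exponential from ~2000 points where bias, not variance, dominates.
* Power: two-sided two-sample t with equal group sizes, df `2n-2`,
  noncentrality `delta sqrt(n/2) / sigma`, per-test alpha = family
  alpha (0.1) / number of proteins (Bonferroni).  `delta = 1` log2 unit
  encodes a two-fold change.  scipy's noncentral t returns NaN in far
  tails; those tails are patched with the Johnson–Kotz normal
  approximation (agreement with statsmodels' power solver to 1e-8
  elsewhere).  `sigma = 0` yields power 1 by convention.
* The coverage table reports, per candidate group size, the percentage
  of proteins whose power meets each target (defaults 95/75/50%);
  per-protein sigmas default to the loess-smoothed CV at each protein's
  abundance.  `required_n` finds the smallest group size meeting a
  target by bracketed monotone search and returns a sentinel when the
  cap is exceeded.

## Enrichment

Weighted Kolmogorov–Smirnov running sum with weight p = 1: hits add
`|score|^p / Σ_set |score|^p`, misses subtract `1/(N - |set|)`; ES is
the extremum; the leading edge (core genes) contains members at or
before (positive ES) / at or after (negative ES) the extremum.  The
null is gene-set permutation (size-matched random draws) — sample-level
phenotype permutation is unavailable when comparing fixed protein sets
against one ranked list.  NES divides ES by the mean same-sign null
magnitude; multi-set FDR follows the pooled-NES tail-ratio procedure.
Up- and down-regulated protein sets are tested separately.  The ranked
signature used by the analysis scripts is synthetic (ground-truth fold
changes plus unit noise, labelled as such); no external mRNA data are
bundled.

## Problem sizes and numerical choices

Simulation sizes are chosen for single-core desk-scale runs: validation
experiments use 2000 proteins (≥ 50 per abundance decile after
splitting), the Monte-Carlo power oracle uses 1e5 replicates per grid
cell, permutation tests 200–1000 permutations, and the analysis scripts
a 1200-protein study.  Ties in the gene ranking are broken by gene id;
BH uses a stable mergesort; matrices are written with 10 significant
digits, which bounds round-trip error in all file-based workflows.

## Known limitations

* Protein-level simulation only; no peptide roll-up, retention-time or
  spectral structure.
* The dropout model and its rate are conventions, not estimates.
* The batch-in-model ρ̂ is a pooled approximation; per-protein
  correlations and REML estimation are out of scope.
* Nonparametric empirical-Bayes priors and reference-batch correction
  are not implemented.
* Power analysis assumes equal group sizes and the two-sample t family;
  power for the partial-correlation analysis is not modelled.
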