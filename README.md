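# cordmeth

Analysis pipeline for umbilical-cord-blood DNA methylation studies of prenatal
exposures: pediatric (gestational) epigenetic clocks, reference-based blood
cell-type deconvolution, EWAS-derived epigenetic scores, and a rank-based /
inverse-Gaussian-GLM inference suite — plus a synthetic cohort generator with
recorded ground truth, so that every stage of the chain has a recovery test.

It is aimed at epigenomics researchers who analyse Illumina-array beta values
(methylation fractions in [0, 1]) from birth cohorts with a binary exposure
contrast — here, prenatal cocaine exposure (PCE) versus controls — and who
want the whole chain from probe QC to group inference reproducible from a
single seed.

## The methods at the core

**Epigenetic gestational age (DNAmGA).** A pediatric clock is an affine map
from clock-CpG betas to gestational age,
`DNAmGA(s) = a + Σᵢ wᵢ·β(i, s)`, with day-native clocks converted to weeks.
**GA acceleration** is the residual of OLS of DNAmGA on chronological GA,
fit on the pooled cohort; negative residuals are epigenetic *deceleration*.

**Cell-type deconvolution.** Per sample, fractions solve the constrained
projection `min‖Sᵀf − β‖²` subject to `f ≥ 0, Σf = 1` (nonnegative least
squares with a weighted sum-to-one row), against a cell-type × probe
signature matrix (CD4T, CD8T, monocytes, nucleated red blood cells,
neutrophils for cord blood).

**Epigenetic scores (ES).** Each phenotype panel carries per-CpG EWAS
coefficients `cᵢ` and a hyper/hypo direction. Weights are
`wᵢ = |cᵢ| / mean|c|`; the raw score per sample is
`Σ_hyper (βᵢ − cᵢ)wᵢ + Σ_hypo (cᵢ − βᵢ)wᵢ`, Z-scored over the pooled cohort.
Panels are thresholded at source-EWAS p ≤ 1e-5.

**Inference.** Mann–Whitney U (tie-corrected normal approximation) for
continuous contrasts, Pearson chi-square *without* continuity correction for
categorical ones, Spearman's rho for correlations, and inverse-Gaussian
identity-link GLMs on the acceleration shifted by +10 (to keep the response
positive), with per-covariate Wald tests and an omnibus deviance test against
the intercept-only model.

## Worked example

```
python analysis/01_simulate_cohort.py
python analysis/02_run_pipeline.py
```

prints (seed 0):

```
QC: 486 probes -> 471 retained (15 removed)
toy_clock_50: DNAmGA vs chronological GA rho = 0.54 (p = 1.93e-07)
  * accel_toy_clock_50                 exposed   -1.83 vs control    1.33  U = 0.0, p = 1.3e-14
  * es_gestational_smoking             exposed    1.15 vs control   -0.85  U = 1645.0, p = 1.3e-14
  * es_adulthood_smoking               exposed    1.14 vs control   -0.85  U = 1645.0, p = 1.3e-14
  * es_psychosis                       exposed    1.16 vs control   -0.86  U = 1645.0, p = 1.3e-14
    es_autism                          exposed    0.09 vs control    0.15  U = 791.0, p = 0.771
  * es_diabetes                        exposed    1.16 vs control   -0.86  U = 1645.0, p = 1.3e-14
    es_obesity                         exposed   -0.29 vs control    0.20  U = 624.0, p = 0.0634
BDNF vs acceleration: rho = -0.62 (p = 6.51e-10)
GLM group coefficient = -3.073 weeks (Wald p = 0.00879); omnibus chi2 = 1144.6 (p = 1.38e-238)
```

Reading: the 15 removed probes are the planted QC decoys (sex-chromosome,
SNP-proximal, cross-reactive, detection-failing). The exposed group shows the
planted epigenetic-GA deceleration (median acceleration −1.83 vs +1.33 weeks;
U = 0 means complete group separation), the four planted ES panels are shifted
upward while autism and obesity stay null, serum BDNF rises as acceleration
falls (negative rho), and the GLM recovers a negative group coefficient close
to the planted −3 weeks after adjusting for cell composition and obstetric
covariates.

`analysis/03_published_count_statistics.py` recomputes the four categorical
group contrasts of the source cohort's demographic table from printed counts
(chi-squares 0.230, 26.69, 17.07, 52.56), and
`analysis/04_recovery_and_calibration.py` re-measures effect recovery and
null calibration over reseeded replicates.

A `cordmeth` console script exposes the same pipeline
(`cordmeth simulate`, `cordmeth run`, `cordmeth report`); the library API is
importable as `cordmeth`.

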