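# Methods

## What the pipeline models

The package analyses cord-blood DNA methylation beta matrices (probes ×
samples, values in [0, 1]) for a binary prenatal-exposure contrast. Five
computational stages are chained: probe-level QC and full-quantile
normalization; linear epigenetic-clock prediction of gestational age
(DNAmGA) with residual-based acceleration; constrained-projection cell-type
deconvolution; EWAS-derived epigenetic scores (ES); and a group-inference
suite (Mann–Whitney, chi-square, Spearman, inverse-Gaussian identity-link
GLM). Because the motivating cohort data are not publicly deposited, the
package ships a synthetic cohort generator whose planted effects make every
stage verifiable: each analysis has a recovery test against recorded ground
truth rather than against irreproducible cohort medians.

## QC and normalization

Probes are removed when they (a) map to a sex chromosome (labels X/Y,
chrX/chrY, case-insensitive), (b) are annotated SNP-proximal, (c) are
annotated cross-reactive, or (d) fail detection in **one or more** samples.
A probe fails detection in a sample when its detection p ≥ 0.05: small
detection p means reliable signal, so the standard convention is the
default; the comparison direction is configurable (`fail_when="lt"`) for
pipelines whose detection statistic is oriented the other way. Filtering is
pure row selection — retained values are never altered — and idempotent.

Normalization is full-quantile onto the across-sample mean of order
statistics. Within-column rank order is preserved; tied input values
receive the mean of the reference values at the tied positions (midrank
rule). A consequence worth knowing: with ties the columns' sorted multisets
agree only up to that averaging; they are exactly identical for tie-free
columns. Array-type-stratified normalization and dye-bias/background
correction are out of scope — the pipeline operates downstream of any
array-specific correction.

## Clocks and acceleration

A clock is `DNAmGA(s) = intercept + Σᵢ wᵢ β(i, s)`; day-native clocks (the
Bohlin-style convention) are divided by 7 at prediction time so every
downstream quantity is in weeks. Published coefficient tables load through
a two-column CSV (`probe_id, coefficient` with one `(Intercept)` row) plus
a JSON sidecar for name and units; no coefficient tables are bundled.
Missing clock probes are cohort-mean imputed when partially observed and
dropped (with a logged warning) when entirely absent; a `strict` policy
raises instead.

Acceleration is the residual of OLS of DNAmGA on chronological GA with
intercept, fit on the **pooled** cohort (groups together). Pooling is what
lets a group contrast in DNAmGA survive into the residuals — per-group
regressions would absorb it. Residuals sum to zero and are orthogonal to GA
by construction, and are invariant to affine rescaling of GA.

Note on the two-step estimator: regressing out GA and then contrasting
residual means slightly attenuates a planted group effect, by a factor of
order 1/n through the sample covariance between group and GA. The replicate
tests therefore check unbiasedness with the joint GA+group regression and
allow the two-step contrast its textbook attenuation (≈ 1–2% at n = 82).

## Cell-type deconvolution

Per sample the fractions solve `min ‖Sᵀf − β‖²` s.t. `f ≥ 0`, `Σf = 1`,
the canonical constrained-projection formulation. The solver is
nonnegative least squares on a design augmented with a sum-to-one row
weighted at 1e4 × the maximum signature magnitude, followed by an exact
simplex renormalization; this is reproducible without a QP dependency and
keeps the Σf = 1 tolerance (1e-6) testable. The probes used are the
intersection of the beta matrix and the reference; no signature-probe
selection is performed (the synthetic references are discriminative by
construction). A rank-deficient signature on the shared probes, or fewer
shared probes than cell types, is an error. Robust-partial-correlation
variants and reference construction from sorted cells are out of scope.

## Epigenetic scores

Weights divide each CpG's EWAS coefficient by the panel mean. The default
`absolute` mode uses magnitudes, `wᵢ = |cᵢ|/mean|c|`, with the disease
direction carried entirely by the hyper/hypo flag: a mixed-direction panel
can have a signed mean arbitrarily close to zero, which would explode
signed weights. The literal `signed` mode (`wᵢ = cᵢ/mean c`) is available
and errors when |mean c| < 1e-12. Raw scores sum weighted directional
deviations of sample betas from the reference coefficients (treated as
beta-scale constants); Z-scoring uses the pooled cohort mean and sd (n−1),
since groups are compared after transformation and must share one scale.
The panel stringency filter keeps source p ≤ 1e-5 — inclusive at the
boundary, reading "at least as stringent" literally. The six default panel
sizes (19 gestational smoking, 15 adult smoking, 72 psychosis, 6 autism,
68 diabetes, 41 obesity) match the source EWAS panels.

## Inference suite

- **Mann–Whitney U**: U counts pairs where the first (exposure) group wins,
  plus half the ties; two-sided p from the tie-corrected normal
  approximation with continuity correction (exact enumeration is used
  automatically for small tie-free samples, n₁n₂ ≤ 400). Which group's U is
  reported is a convention; first-group is fixed here.
- **Pearson chi-square**: no Yates continuity correction by default — the
  convention under which published 2×2 statistics are exactly reproducible
  from printed counts (verified for all four reconstructible tables); a
  corrected option exists.
- **Spearman**: Pearson correlation of midranks, p via the t-approximation
  on n−2 df.
- **Inverse-Gaussian GLM, identity link**: the acceleration response is
  shifted by +10 (configurable) so the strictly-positive support holds;
  fitting is IRLS (statsmodels), dispersion is Pearson X²/(n−p), Wald is
  (β/SE)² against χ²(1), and the omnibus statistic is the
  dispersion-scaled deviance drop from the intercept-only model against
  χ²(p−1). The omnibus construction is a documented choice; published
  omnibus values are not used as references. The default covariate set is
  Apgar, birth weight, maternal infectious disease, ethnicity, maternal
  age, CD4T, CD8T, neutrophils, nRBC, the gestational-smoking ES, and
  group; it is configurable (monocytes can be added).

No multiple-testing correction is applied in the group-comparison tables,
matching the source analysis design; t-tests exist nowhere in the default
path because the modelled variables are non-normal.

## Synthetic cohorts

The generator plants the effect structure the analysis is meant to detect,
with one named random sub-stream per component (CRC32 of the component name
mixed into the seed sequence) so adding a component never perturbs others.

- **Design**: 35 exposed / 47 control samples; chronological GA uniform on
  37–41 weeks (term births).
- **Clock probes**: betas solve the under-determined linear system so the
  noiseless prediction equals true GA plus the planted group shift. The
  solution is the minimum-norm adjustment of a random baseline in
  [0.3, 0.7], recentred (two clamped passes) so the baseline's prediction
  sits at the mid-target; values are clipped to [0, 1] and the generator
  warns if clipping moves any pre-noise beta by > 1e-6.
- **Planted deceleration**: −3.0 weeks by default. The source cohort
  reports only observed acceleration medians (clock-dependent contrasts of
  roughly −3 to −7.6 weeks); −3.0 is chosen once as a conservative,
  realistic magnitude.
- **Cell composition**: baseline simplex (CD4T .15, CD8T .10, mono .08,
  nRBC .17, neutrophils .50 — a plausible cord-blood profile), exposed-group
  shift (+.06, +.04, 0, −.04, −.06) applied then renormalized, per-sample
  Dirichlet draws at concentration 200. Mixture probes are `fᵀS` plus
  noise.
- **ES probes**: baseline betas uniform [0.2, 0.8]; the exposed group is
  shifted by 0.05 in each probe's disease direction for the four planted
  phenotypes (both smoking panels, psychosis, diabetes); autism and obesity
  stay null.
- **BDNF**: linear-Gaussian in the planted acceleration,
  25 − 1.5 × acceleration ± 2 ng/mL. Only a monotone negative association
  is asserted by the source, so monotone-linear is the simplest sufficient
  structure.
- **Noise**: additive Gaussian on betas, sd 0.01 (EPIC-scale technical
  noise), clipped to [0, 1].
- **Covariates**: group contrasts sized from the source cohort's
  demographic table (Apgar −1, weight −88 g, maternal age +2 y, infectious
  disease 46% vs 0, white ethnicity 29% vs 74%, tobacco 89% vs 9%); a
  `covariate_effects=False` switch produces fully null cohorts for
  calibration runs.
- **QC decoys**: a few extra junk probes flagged sex-chromosome /
  SNP-proximal / cross-reactive / detection-failing, disjoint from all
  signal probes, so filtering tests never touch planted structure.

What the generator does **not** emulate: IDAT/manifest structure,
batch/chip effects, probe-type chemistry differences, genetic (SNP)
confounding, spatial correlation among CpGs, and realistic beta
distributions (real arrays are bimodal; the mixtures here are not).
Passing recovery tests therefore demonstrates the correctness of the
computational chain under the assumed generative model — not robustness to
the artefacts of real arrays.

## Problem sizes and numerical choices

Replicate suites use 200 cohorts for effect recovery and power, 500
effect-free cohorts (with a reduced probe set: 20 clock probes, one ES
panel, 2 cell types) for type-I calibration, and 200 × n = 2000 draws for
GLM coefficient recovery; these sizes give Monte-Carlo standard errors
comfortably below the tested tolerances. GLM convergence is |Δ| < 1e-8 or
100 iterations, with non-convergence flagged but results returned.
Quantile-normalization ties use the midrank rule; NNLS degeneracy (all-zero
fractions) and constant-GA regressions raise rather than guess. File
round-trips write floats at 17 significant digits and read them back with
round-trip parsing, so serialized cohorts are bit-exact.

## Known limitations

- The toy clocks are random linear maps, not trained predictors; published
  clock coefficient tables must be supplied by the user through the clock
  CSV format (they are not redistributed here).
- The real cord-blood reference matrix is likewise not bundled; the
  deconvolution is validated on synthetic signatures only.
- The constrained-projection deconvolution is a canonical formulation, not
  a re-implementation of any specific published estimator's internals.
- Gene-ontology/pathway enrichment of ES CpGs is out of scope (it depends
  on external, versioned annotation databases).
- With default effect sizes the synthetic group contrasts are stronger than
  typical real-cohort contrasts (complete separation in the U tests); the
  defaults prioritize unambiguous recovery testing over realism.
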