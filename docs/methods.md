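# Methods

This note documents the models the package implements, the defaults it
ships, and the design decisions taken where the underlying procedure left
choices open.

## Microstructural integrity index (MII)

Skeletonized diffusion metrics (FA, MD, AD, RD) are compared voxel-wise
against the healthy-control distribution.  For metric value `x_v` of a
subject at skeleton voxel `v`:

    z_v = (x_v − x̄_v) / s_v

with `x̄_v` the control mean and `s_v` the control dispersion at that voxel.

- **Dispersion.** The z-score denominator is the sample standard deviation
  (n − 1), the standard normative-z denominator; a `ddof=0` switch selects
  the population SD.  (A mean-signed-deviation reading of the dispersion is
  identically zero and therefore not a usable denominator.)
- **Normative design.** Patients contribute nothing to the control
  statistics.
- **Skeleton selection.** Voxels with mean control FA ≥ 0.2 form the
  skeleton; the comparison is inclusive (≥), matching common imaging-tool
  semantics, and configurable.
- **Lesion masks.** Interpolated (soft) masks are thresholded at 0.5
  (inclusive) and binarized; the operation is idempotent and monotone in
  the threshold.
- **Zero-dispersion voxels** are flagged, logged and excluded from z-maps
  rather than erroring — real skeletons can contain constant voxels.
- **Regional summaries.** For each patient, metric, and region (lesion =
  mask 1, NAWM = mask 0), the summary is
  `100 · mean(patient values) / mean(control mean)` (percent of control).
  Because the percent convention is not uniquely determined, the mean-z
  variant over the same voxels is always co-emitted so downstream analyses
  can use either.  A patient with no lesion voxels gets a missing lesion
  summary (logged); an empty NAWM region is treated as a pathological mask
  and is an error.

Identities used as tests: a patient equal to the control mean has an
all-zero z-map and 100% of control everywhere; averaging the controls' own
z-maps gives 0 per voxel to machine precision; z-maps are invariant under
any common affine rescaling of a metric.

## PLS1 with permutation inference and VIP

One univariate-outcome PLS model per outcome (EDSS, BVMT-R, CVLT-II,
SDMT), fitted by NIPALS with X-deflation only; for univariate outcomes
this spans the same fitted subspace as SIMPLS.  Per component `a`:
`w_a ∝ X_aᵀ y_a` (unit norm), `t_a = X_a w_a`, `p_a = X_aᵀ t_a / t_aᵀt_a`,
`q_a = y_aᵀ t_a / t_aᵀt_a`, then deflation of both `X` and `y`.

- **Standardization.** Predictor columns are scaled to unit sample SD and
  the outcome centered before fitting.  The predictors mix mm³, years, a
  binary indicator and percent summaries; without standardization the VIP
  ranking would be scale-driven.  A flag disables it.
- **Permutation test.** The per-component statistic is the leading singular
  value of the deflated cross-covariance, `‖X_aᵀ y_a‖` for univariate y.
  The outcome is permuted (fresh permutation per draw, default 5,000
  draws), components are re-fit on the permuted data, and p-values use the
  add-one rule `p = (1 + #{null ≥ obs}) / (1 + n_perm)`, so p is never 0.
  Components beyond the first are tested on deflated matrices — a
  per-component scheme, documented as this package's choice.
- **Retention rule.** Keep the largest prefix of components with p ≤ α
  (default 0.05) and outcome-variance share ≥ 10%; the first component is
  retained on significance alone.  If component 1 is not significant the
  model is reported as having no significant latent variable (VIP scores
  are still emitted, computed from component 1, but flagged).
- **VIP.** `VIP_j = sqrt(p · Σ_a ssY_a w_ja² / Σ_a ssY_a)`; with unit-norm
  weights the squared scores average exactly 1 over the p predictors
  (checked to 1e-8), and selection uses the strict VIP > 1 rule.  VIP is
  computed on the retained components only.
- **Sign convention.** The first non-negligible entry of each weight vector
  is made positive, for reproducible loadings across platforms.
- **Degenerate inputs.** Constant predictor columns, constant outcomes,
  requests beyond the matrix rank, and exhausted cross-covariance all raise
  named errors; missing cells are rejected with the offending
  subject/column listed (complete-case analysis only).

Oracle checks: the component-1 weight equals the normalized
cross-covariance vector; full-rank PLS1 reproduces the OLS fit to 1e-6;
fitted values match scikit-learn's PLSRegression (used only as an
independent cross-check, never as the implementation).

## Synthetic cohort generator

The generator emulates the structure of a 53-patient / 53-control
relapsing-remitting MS imaging study so that every stage can be tested
against planted ground truth.

| Parameter | Default | Why |
|---|---|---|
| n_controls / n_patients | 53 / 53 | study-scale cohort |
| n_voxels | 2,000 | desk-scale skeleton; voxels are i.i.d., so summary behavior depends on count only through averaging error |
| control mean (FA, MD, AD, RD) | 0.50, 0.80, 1.20, 0.60 | typical skeleton values; diffusivities in 1e-3 mm²/s |
| control SD | 10% CV | typical voxel-wise variability |
| NAWM shift (SD units) | −0.554, +0.384, +0.085, +0.806 | derived so percent-of-control ≈ 94.5 / 103.8 / 100.9 / 108.1 |
| lesion shift (SD units) | −1.010, +1.283, +0.566, +2.363 | derived so lesion percents ≈ 89.9 / 112.8 / 105.7 / 123.6 |
| lesion_fraction | 0.05 | ~9,700 mm³ lesion load on a 194,000 mm³ reference skeleton |
| predictor_correlation ρ | 0.3 | moderate collinearity of the volumetric block |
| volume means/SDs | study-scale mm³ values | realistic scales; predictors are standardized downstream, so SDs only shape conditioning |
| effect sizes | 4–5 active per outcome, |β| = 0.5 | sparse ground truth; signs physiologic (atrophy/damage → worse status) |
| noise_sd | 1.0 | planted R² ≈ 0.5 per outcome |
| age | Normal(44.34, 11.51), gender Bernoulli(17/53) | patient demographics |
| EDSS scale | mean 1.89, SD 1.65, clipped [0, 10], 0.5 steps | mild-to-moderate disability cohort |

Outcomes are `y* = Σ_j β_j · standardized(x_j) + Normal(0, noise_sd)`,
affinely placed on the clinical scale; a zero-variance active predictor
(e.g. lesion summaries in a lesion-free configuration) contributes no
signal, and a patient with no lesion voxels receives the no-lesion baseline
of 100% for its lesion summaries.

What the generator deliberately does **not** model, and hence what passing
tests do not show about real data:

- **Spatial structure.** Voxels are i.i.d.; there is no autocorrelation,
  registration error, or anatomy.  No downstream stage uses adjacency, so
  this does not affect the statistics tested.
- **Between-patient severity heterogeneity.** The NAWM/lesion shifts are
  the same for every patient, so the between-patient variance of the
  diffusion summaries comes from voxel-averaging noise alone and is smaller
  than in real cohorts (where diffuse damage severity varies).  The
  summaries remain valid standardized predictors, but their raw SDs are
  not calibrated to reported cohort SDs.
- **EDSS ordinality** beyond clipping to [0, 10] and rounding to 0.5 steps.
  The clipping/rounding attenuates correlations; with the default planted
  effects, the EDSS first latent variable clears α = 0.05 in ≈ 85% of seeds
  rather than essentially always, which the worked example reports
  honestly.
- **Scanner noise, longitudinal follow-up, treatment effects.**

### Parameter-recovery experiment

The recovery experiment (`simulate_recovery_dataset`) uses the one-factor
collinearity design across all 26 predictors (pairwise correlation
ρ = 0.3), with four active predictors at effect 0.5 SD and unit noise.
Actives share a sign: on positively equicorrelated predictors, mixed-sign
effects cancel in the cross-covariance (a −0.5 active among three +0.5
actives has population covariance −0.5 + 0.3 · 1.5 = −0.05 with the
outcome), making the negative effect unrecoverable by any
covariance-driven selector — a property of the design, not of the
implementation.  Under the default design, latent variable 1 is flagged
significant in 100% of 50 seeds and VIP > 1 sensitivity is 0.97.

### Problem sizes

Default experiment sizes — 2,000 skeleton voxels, 500 null-calibration
replicates at 199 permutations, 50 recovery seeds at 499 permutations —
were chosen so the full analysis and test suite run comfortably on a
laptop-class single core while keeping Monte-Carlo error well inside the
asserted bounds (e.g. the 95% binomial band for the null rejection rate at
500 replicates is ±0.019).

## Cognitive impairment classification

A BICAMS subtest score is called impaired when it deviates from the
user-supplied normative mean by strictly more than two normative SDs in
the adverse direction (lower-is-worse for all three subtests).  Normative
means/SDs are user-supplied because published normative databases are not
redistributable in machine-readable form.  Patient-level flags are
summarized as counts impaired on exactly 0–3 subtests.

## Known limitations

- Real-data mode expects pre-computed skeletonized metrics and projected
  lesion masks (TSV or NIfTI); registration, skeleton projection and tensor
  fitting are upstream of this package.
- Only univariate-outcome PLS is implemented (no PLS2, kernel or sparse
  PLS, no cross-validated component selection).
- The per-component permutation scheme on deflated matrices is one of
  several defensible schemes for testing later latent variables; results
  for component 1 are scheme-independent.
- Disease duration and therapy variables are not part of the predictor
  set.
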