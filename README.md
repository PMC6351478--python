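# mspls

Multiparametric MRI predictors of clinical and cognitive disability in
multiple sclerosis (MS): voxel-wise microstructural integrity indexing of
skeletonized diffusion maps, lesion / normal-appearing white matter (NAWM)
summarization, and partial least squares (PLS) regression with permutation
inference and VIP-based variable selection.

## The problem

MS pathology is multifaceted — focal white-matter lesions, gray-matter
atrophy, and diffuse microstructural damage in tissue that looks normal on
conventional images.  MRI yields many correlated candidate markers (lesion
load, brain/GM/WM volumes, subcortical structure volumes, diffusion-tensor
summaries), and ordinary regression cannot rank their contributions in the
presence of that collinearity.  This package implements the model-free
analysis chain used to ask which markers best predict a patient's clinical
disability (EDSS) and cognition (BICAMS subtests: SDMT, CVLT-II, BVMT-R):

1. **Microstructural integrity index (MII).**  On a white-matter skeleton
   (voxels with mean FA ≥ 0.2), each patient's diffusion value is z-scored
   against the control cohort voxel-wise:
   `z_v = (x_v − x̄_v) / s_v`, with `x̄_v`, `s_v` the control mean and
   sample SD of voxel `v`.  Averaging z over the skeleton gives a global
   damage score; averaging raw values inside / outside the projected lesion
   mask (thresholded at 0.5 and binarized) gives lesion and NAWM summaries
   as percent of the control regional mean, for each of FA, MD, AD, RD.
2. **PLS1 with permutation inference.**  With the 26-column standardized
   predictor matrix `X` and one outcome `y`, PLS extracts latent variables
   `X = T Pᵀ + E`, `y = T qᵀ + F` maximizing outcome covariance.  Each
   latent variable is tested by permuting `y` (5,000 times by default) and
   recomputing the leading singular value of the deflated cross-covariance
   `‖X_aᵀ y_a‖`.
3. **VIP selection.**  Predictor importance is
   `VIP_j = sqrt( p · Σ_a ssY_a w_ja² / Σ_a ssY_a )`; squared VIPs average
   exactly 1, so predictors with VIP > 1 are called important.

Because per-patient clinical data of the motivating study are not publicly
deposited, the package ships a synthetic cohort generator that emulates the
study's structure (53 patients + 53 controls, four diffusion metrics on a
shared skeleton, collinear volumetric predictors on realistic mm³ scales,
outcomes from a known sparse linear model), so every stage is testable
against planted ground truth.

## Worked example

```bash
mspls run-all --mode synth --out results/demo --seed 1 --n-perm 5000
mspls report --report results/demo/report.json
```

or, through the analysis drivers:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_mii_summaries.py
python analysis/03_pls_analysis.py
```

Driver 02 prints the regional summaries of the simulated cohort (percent of
control; the generator is parameterized so these sit on realistic MS
scales — reduced FA, elevated diffusivities, worse inside lesions):

```
mean percent-of-control by metric and region:
region  lesion    nawm
metric
ad      105.61  100.84
fa       89.81   94.47
md      112.96  103.83
rd      123.42  108.05
```

Driver 03 then fits one PLS per outcome (seed 1, 5,000 permutations).  For
visuo-spatial memory it prints:

```
Outcome: BVMT
  retained latent variables: 1
    LV1: 40.64% of outcome variance, 19.34% of predictors, p = 0.0007998
    LV2: 23.58% of outcome variance, 8.94% of predictors, p = 0.05839
  predictors with VIP > 1:
    right_hippocampus: VIP = 1.800
    pbv: VIP = 1.528
    nawm_ad: VIP = 1.454
    lesion_load: VIP = 1.440
    left_hippocampus: VIP = 1.375
    ...
recovery vs ground truth:
  bvmt: 3/4 planted predictors selected; ...
  sdmt: 4/4 planted predictors selected; false alarms ['gm_volume', 'nawm_md', 'pbv', 'right_caudate']
```

The first latent variable is significant by permutation test, the second is
dropped by the retention rule (< 10% of outcome variance or non-significant),
and the VIP > 1 rule recovers most of the predictors the generator actually
used to build each outcome — here both hippocampi and NAWM axial
diffusivity for BVMT — at the cost of some false alarms among the 22
inactive but collinear predictors.  On this seed the EDSS analysis is
honestly reported as having *no significant latent variable*
(LV1 p = 0.074): the ordinal clipping/rounding of EDSS costs power at
n = 53, so its first latent variable clears α = 0.05 in roughly 85% of
seeds rather than always (see `docs/methods.md`).

Drivers 04 and 05 characterize the inference: under a global null
(outcome independent of the collinear predictors) the permutation test
rejects at `0.046` with uniform p-values (KS p = 0.094), and across 50
planted-effect datasets latent variable 1 is flagged significant in 100% of
seeds with VIP sensitivity 0.97.

## Layout

- `src/mspls/` — library: `synth` (cohort generator), `mii` (z-scoring and
  regional summaries), `pls` (PLS1 / permutation / VIP), `pipeline`
  (per-outcome analyses, impairment rules), `io` + `cli`.
- `analysis/` — numbered narrative drivers writing under `results/`.
- `tests/` — pytest suite, including end-to-end scientific checks.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
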