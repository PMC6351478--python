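"""Synthetic MS cohort generator with known ground truth.

Emulates the structure of a relapsing-remitting MS imaging study: 53
patients and 53 healthy controls carrying four diffusion metrics (FA, MD,
AD, RD) on a shared white-matter skeleton, per-patient lesion masks,
collinear volumetric predictors on realistic mm^3 scales, demographics, and
clinical/cognitive outcomes (EDSS, BVMT-R, CVLT-II, SDMT) produced by a
sparse linear latent model whose active predictors and effect sizes are
recorded as ground truth.  Every downstream stage of the package is
testable against that ground truth without any external data.

Generative model
----------------
* Control voxels: i.i.d. Normal(control_mean, control_sd) per metric.
  Voxels are spatially independent; no downstream stage uses adjacency.
* Patients: a Bernoulli(lesion_fraction) lesion mask per patient; NAWM
  voxels are shifted by ``nawm_shift`` control-SDs, lesioned voxels by
  ``lesion_shift`` control-SDs.  Default shifts are chosen so that the
  lesion/NAWM percent-of-control summaries land on the study's reported
  scales under a 10% coefficient of variation.
* Volumetric predictors and age: a one-factor collinearity model
  ``z_j = sqrt(rho) f + sqrt(1 - rho) e_j`` rescaled to per-structure
  means/SDs; gender is Bernoulli(17/53).
* Outcomes: ``y* = sum_j beta_j standardized(x_j) + Normal(0, noise_sd)``
  over each outcome's active predictor set, affinely placed on the clinical
  scale; EDSS is additionally clipped to [0, 10] and rounded to 0.5 steps.

Everything is reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import mii
from .errors import ConfigurationError, DataError
from .mii import CONTROL, PATIENT, METRICS, SkeletonCohort
from .pipeline import OUTCOME_COLUMNS, PREDICTOR_COLUMNS

# control distribution per metric: (mean, SD); FA unitless, diffusivities in
# 1e-3 mm^2/s.  10% coefficient of variation throughout.
DEFAULT_CONTROL_MEAN = {"fa": 0.50, "md": 0.80, "ad": 1.20, "rd": 0.60}
DEFAULT_CONTROL_SD = {m: 0.1 * v for m, v in DEFAULT_CONTROL_MEAN.items()}

# shifts in control-SD units; chosen so percent-of-control regional means
# reproduce the study-scale values (e.g. NAWM FA ~94.5%, lesion RD ~123.6%)
# under the 10% CV above: shift = (percent/100 - 1) / CV.
DEFAULT_NAWM_SHIFT = {"fa": -0.554, "md": 0.384, "ad": 0.085, "rd": 0.806}
DEFAULT_LESION_SHIFT = {"fa": -1.010, "md": 1.283, "ad": 0.566, "rd": 2.363}

# volumetric scales (mm^3): patient-group means/SDs of the emulated study
DEFAULT_VOLUME_MEANS = {
    "pbv": 1423745.72,
    "gm_volume": 784317.27,
    "wm_volume": 639428.45,
    "left_amygdala": 1717.22,
    "right_amygdala": 1666.32,
    "left_caudate": 4324.02,
    "right_caudate": 4414.96,
    "left_hippocampus": 5019.21,
    "right_hippocampus": 5148.92,
    "left_pallidum": 2303.76,
    "right_pallidum": 2331.54,
    "left_putamen": 6270.55,
    "right_putamen": 6248.99,
    "left_thalamus": 9653.80,
    "right_thalamus": 9380.61,
}
DEFAULT_VOLUME_SDS = {
    "pbv": 7726.26,
    "gm_volume": 51061.79,
    "wm_volume": 43973.57,
    "left_amygdala": 304.80,
    "right_amygdala": 264.20,
    "left_caudate": 611.32,
    "right_caudate": 705.49,
    "left_hippocampus": 608.16,
    "right_hippocampus": 551.24,
    "left_pallidum": 328.13,
    "right_pallidum": 250.36,
    "left_putamen": 749.85,
    "right_putamen": 765.47,
    "left_thalamus": 1092.74,
    "right_thalamus": 1092.52,
}

# sparse ground truth per outcome, |effect| = 0.5 outcome-SD units, signs
# physiologic (higher diffusivity / lower FA / smaller volumes -> worse
# status; EDSS increases with disability, the cognitive raw scores
# decrease).  The EDSS set mirrors the predictors the emulated study found
# important for clinical disability (age and NAWM/lesion diffusion).
DEFAULT_EFFECT_SIZES: dict[str, dict[str, float]] = {
    "edss": {
        "age": 0.5,
        "nawm_ad": 0.5,
        "nawm_md": 0.5,
        "lesion_fa": -0.5,
        "lesion_rd": 0.5,
    },
    "bvmt": {
        "left_hippocampus": 0.5,
        "right_hippocampus": 0.5,
        "lesion_fa": 0.5,
        "nawm_ad": -0.5,
    },
    "cvlt": {
        "right_hippocampus": 0.5,
        "lesion_load": -0.5,
        "pbv": 0.5,
        "nawm_fa": 0.5,
    },
    "sdmt": {
        "nawm_fa": 0.5,
        "nawm_rd": -0.5,
        "lesion_md": -0.5,
        "right_hippocampus": 0.5,
    },
}

# clinical scales the raw outcomes are placed on: (mean, SD)
DEFAULT_OUTCOME_SCALES = {
    "edss": (1.89, 1.65),
    "bvmt": (20.0, 8.0),
    "cvlt": (45.0, 12.0),
    "sdmt": (45.0, 12.0),
}

DEFAULT_AGE = (44.34, 11.51)  # patient years
DEFAULT_MALE_FRACTION = 17 / 53
# reference skeleton volume (mm^3) converting lesioned-voxel fraction into a
# lesion load on the study's printed scale (mean load ~9700 mm^3 at 5%)
DEFAULT_SKELETON_VOLUME = 194_000.0

_DIFFUSION_COLUMNS = tuple(f"{r}_{m}" for r in ("nawm", "lesion") for m in METRICS)
_VOLUME_COLUMNS = tuple(DEFAULT_VOLUME_MEANS)


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n_controls: int = 53
    n_patients: int = 53
    n_voxels: int = 2000
    metrics: tuple[str, ...] = METRICS
    control_mean: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_MEAN)
    )
    control_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_SD)
    )
    nawm_shift: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NAWM_SHIFT)
    )
    lesion_shift: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LESION_SHIFT)
    )
    lesion_fraction: float = 0.05
    volume_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VOLUME_MEANS)
    )
    volume_sds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VOLUME_SDS)
    )
    predictor_correlation: float = 0.3
    effect_sizes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EFFECT_SIZES.items()}
    )
    noise_sd: float = 1.0
    outcome_scales: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_SCALES)
    )
    age_mean: float = DEFAULT_AGE[0]
    age_sd: float = DEFAULT_AGE[1]
    male_fraction: float = DEFAULT_MALE_FRACTION
    skeleton_volume_mm3: float = DEFAULT_SKELETON_VOLUME
    soft_masks: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_controls < 3:
            raise ConfigurationError(f"n_controls must be >= 3, got {self.n_controls}")
        if self.n_patients < 1:
            raise ConfigurationError(f"n_patients must be >= 1, got {self.n_patients}")
        if self.n_voxels < 1:
            raise ConfigurationError(f"n_voxels must be >= 1, got {self.n_voxels}")
        for m in self.metrics:
            for name, table in (
                ("control_mean", self.control_mean),
                ("control_sd", self.control_sd),
                ("nawm_shift", self.nawm_shift),
                ("lesion_shift", self.lesion_shift),
            ):
                if m not in table:
                    raise ConfigurationError(f"{name} missing metric {m!r}")
            if self.control_sd[m] <= 0:
                raise ConfigurationError(
                    f"control_sd[{m!r}] must be > 0, got {self.control_sd[m]}"
                )
        if not 0.0 <= self.lesion_fraction <= 1.0:
            raise ConfigurationError(
                f"lesion_fraction must be in [0, 1], got {self.lesion_fraction}"
            )
        if not 0.0 <= self.predictor_correlation < 1.0:
            raise ConfigurationError(
                "predictor_correlation must be in [0, 1), got "
                f"{self.predictor_correlation}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        generated = set(PREDICTOR_COLUMNS)
        for outcome, effects in self.effect_sizes.items():
            if outcome not in OUTCOME_COLUMNS:
                raise ConfigurationError(f"effect_sizes names unknown outcome {outcome!r}")
            unknown = set(effects) - generated
            if unknown:
                raise ConfigurationError(
                    f"effect_sizes[{outcome!r}] names unknown predictor(s): "
                    f"{sorted(unknown)}"
                )
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError(f"seed must be an integer, got {self.seed!r}")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    active_predictors: dict[str, tuple[str, ...]]
    effect_sizes: dict[str, dict[str, float]]
    lesion_masks: np.ndarray  # n_patients x n_voxels, binary
    linear_predictor: dict[str, np.ndarray]  # per-outcome signal (pre-noise)

    def to_jsonable(self) -> dict:
        return {
            "active_predictors": {k: list(v) for k, v in self.active_predictors.items()},
            "effect_sizes": self.effect_sizes,
            "lesion_masks": self.lesion_masks.astype(int).tolist(),
            "linear_predictor": {
                k: [float(x) for x in v] for k, v in self.linear_predictor.items()
            },
        }


def _spawn(seed: int, label: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(label)]))


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[SkeletonCohort, pd.DataFrame, GroundTruth]:
    """Generate voxel maps, masks, feature table and outcomes in one call.

    Returns ``(cohort, features, truth)`` where ``features`` is a patient-row
    table with the canonical 26 predictor columns plus the four outcomes,
    and the soft lesion masks (when ``config.soft_masks``) are attached to
    the returned ground truth's ``lesion_masks`` binarized form via
    ``features.attrs['soft_masks']``.
    """
    config = config or CohortConfig()
    config.validate()
    n_c, n_p, n_v = config.n_controls, config.n_patients, config.n_voxels

    rng_mask = _spawn(config.seed, 1)
    masks = (rng_mask.random((n_p, n_v)) < config.lesion_fraction).astype(np.uint8)
    soft = None
    if config.soft_masks:
        # soft values straddle the 0.5 binarization threshold on each side
        lo = 0.5 * rng_mask.random((n_p, n_v))
        hi = 0.5 + 0.5 * rng_mask.random((n_p, n_v))
        soft = np.where(masks == 1, hi, lo)

    rng_vox = _spawn(config.seed, 2)
    values: dict[str, np.ndarray] = {}
    for m in config.metrics:
        mu, sd = config.control_mean[m], config.control_sd[m]
        ctrl = rng_vox.normal(mu, sd, size=(n_c, n_v))
        pat = rng_vox.normal(mu, sd, size=(n_p, n_v))
        shift = np.where(masks == 1, config.lesion_shift[m], config.nawm_shift[m])
        pat = pat + shift * sd
        values[m] = np.vstack([ctrl, pat])
    group = np.array([CONTROL] * n_c + [PATIENT] * n_p)
    subject_ids = [f"C{i + 1:03d}" for i in range(n_c)] + [
        f"P{i + 1:03d}" for i in range(n_p)
    ]
    cohort = SkeletonCohort(values=values, group=group, subject_ids=subject_ids)

    # diffusion summaries through the MII machinery itself
    stats = {m: mii.control_voxel_stats(cohort, m) for m in config.metrics}
    summary = mii.regional_summary(cohort, stats, masks)
    # pivot (not pivot_table): all-NaN lesion summaries must survive
    wide = summary.pivot(
        index="subject_id", columns=["region", "metric"], values="percent_of_control"
    )
    patient_ids = subject_ids[n_c:]
    features = pd.DataFrame({"subject_id": patient_ids})
    for region in ("nawm", "lesion"):
        for m in config.metrics:
            col = wide.loc[patient_ids, (region, m)].to_numpy()
            # a patient without lesion voxels deviates nowhere: baseline 100%
            features[f"{region}_{m}"] = np.where(np.isnan(col), 100.0, col)

    # demographics + volumetrics from the one-factor collinearity model
    rng_vol = _spawn(config.seed, 3)
    rho = config.predictor_correlation
    f = rng_vol.normal(size=n_p)
    cols = ("age",) + _VOLUME_COLUMNS
    latent = np.sqrt(rho) * f[:, None] + np.sqrt(1 - rho) * rng_vol.normal(
        size=(n_p, len(cols))
    )
    scales = {"age": (config.age_mean, config.age_sd)}
    scales.update(
        {c: (config.volume_means[c], config.volume_sds[c]) for c in _VOLUME_COLUMNS}
    )
    for j, c in enumerate(cols):
        mu, sd = scales[c]
        features[c] = mu + sd * latent[:, j]
    features["gender"] = (rng_vol.random(n_p) < config.male_fraction).astype(int)
    features["lesion_load"] = masks.mean(axis=1) * config.skeleton_volume_mm3

    features = features[["subject_id", *PREDICTOR_COLUMNS]]

    truth = GroundTruth(
        active_predictors={
            k: tuple(sorted(v)) for k, v in config.effect_sizes.items()
        },
        effect_sizes={k: dict(v) for k, v in config.effect_sizes.items()},
        lesion_masks=masks,
        linear_predictor={},
    )
    outcomes = generate_outcomes(
        features,
        truth,
        noise_sd=config.noise_sd,
        seed=int(_spawn(config.seed, 4).integers(2**31)),
        scales=config.outcome_scales,
    )
    features = pd.concat([features, outcomes], axis=1)
    if soft is not None:
        features.attrs["soft_masks"] = soft
    return cohort, features, truth


def generate_outcomes(
    features: pd.DataFrame,
    truth: GroundTruth,
    noise_sd: float,
    seed: int,
    scales: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Outcome vectors from the sparse linear latent model.

    Each outcome's latent value is the effect-weighted sum of its
    standardized active predictors plus Gaussian noise, affinely placed on
    the outcome's clinical scale.  EDSS is clipped to [0, 10] and rounded to
    the nearest 0.5; cognitive raw scores stay continuous.  The pre-noise
    linear predictor is recorded on ``truth.linear_predictor``.
    """
    scales = dict(scales or DEFAULT_OUTCOME_SCALES)
    rng = np.random.default_rng(seed)
    cells = features[list(PREDICTOR_COLUMNS)].isna()
    if cells.any().any():
        where = [
            (str(features["subject_id"].iloc[i]), cells.columns[j])
            for i, j in zip(*np.where(cells))
        ]
        raise DataError(f"missing feature cells (subject, column): {where}")
    n = len(features)
    out = {}
    for outcome in OUTCOME_COLUMNS:
        effects = truth.effect_sizes.get(outcome, {})
        signal = np.zeros(n)
        for col, beta in effects.items():
            x = features[col].to_numpy(dtype=float)
            sd = x.std(ddof=1)
            if sd == 0:
                # zero-variance predictor carries no signal (e.g. lesion
                # summaries of a lesion-free configuration)
                continue
            signal = signal + beta * (x - x.mean()) / sd
        truth.linear_predictor[outcome] = signal
        latent = signal + rng.normal(0.0, noise_sd, size=n)
        mu, sd_target = scales[outcome]
        spread = latent.std(ddof=1)
        if spread > 0:
            y = mu + sd_target * (latent - latent.mean()) / spread
        else:
            y = np.full(n, mu)
        if outcome == "edss":
            y = np.clip(np.round(y * 2) / 2, 0.0, 10.0)
        out[outcome] = y
    return pd.DataFrame(out, index=features.index)


def simulate_predictor_matrix(
    n: int,
    rho: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Bare 26-column predictor table from the one-factor collinearity model.

    All continuous columns share the factor structure (pairwise correlation
    ``rho``) on their study-scale means/SDs; gender is an independent
    Bernoulli(17/53) indicator.  Intended for null-calibration and
    permutation-uniformity studies, where only the predictor collinearity
    matters and no voxel data is needed.
    """
    if not 0.0 <= rho < 1.0:
        raise ConfigurationError(f"rho must be in [0, 1), got {rho}")
    rng = np.random.default_rng(seed)
    cont = [c for c in PREDICTOR_COLUMNS if c != "gender"]
    scales = {"age": DEFAULT_AGE, "lesion_load": (9698.33, 9754.94)}
    scales.update({c: (DEFAULT_VOLUME_MEANS[c], DEFAULT_VOLUME_SDS[c]) for c in _VOLUME_COLUMNS})
    diffusion_scales = {
        "nawm_fa": (94.46, 5.78),
        "nawm_md": (103.84, 5.14),
        "nawm_ad": (100.85, 2.41),
        "nawm_rd": (108.06, 9.83),
        "lesion_fa": (89.90, 14.36),
        "lesion_md": (112.83, 18.62),
        "lesion_ad": (105.66, 10.07),
        "lesion_rd": (123.63, 35.29),
    }
    scales.update(diffusion_scales)
    f = rng.normal(size=n)
    latent = np.sqrt(rho) * f[:, None] + np.sqrt(1 - rho) * rng.normal(
        size=(n, len(cont))
    )
    df = pd.DataFrame({"subject_id": [f"S{i + 1:03d}" for i in range(n)]})
    for j, c in enumerate(cont):
        mu, sd = scales[c]
        df[c] = mu + sd * latent[:, j]
    df["gender"] = (rng.random(n) < DEFAULT_MALE_FRACTION).astype(int)
    return df[["subject_id", *PREDICTOR_COLUMNS]]


RECOVERY_ACTIVE_SET = ("age", "nawm_ad", "nawm_md", "lesion_rd")


def simulate_recovery_dataset(
    n: int = 53,
    rho: float = 0.3,
    active: Sequence[str] = RECOVERY_ACTIVE_SET,
    effect: float = 0.5,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, tuple[str, ...]]:
    """One parameter-recovery dataset: collinear predictors + sparse outcome.

    Predictors come from :func:`simulate_predictor_matrix` (pairwise
    correlation ``rho``); the outcome is the effect-weighted sum of the
    standardized active predictors plus Normal(0, noise_sd) noise.  Effects
    share a sign because the predictors are positively equicorrelated — a
    coherent disability axis, and the regime in which sparse recovery is
    well-posed.  Returns ``(features, y, active)``.
    """
    df = simulate_predictor_matrix(n, rho=rho, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5]))
    y = np.zeros(n)
    for c in active:
        x = df[c].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise DataError(f"predictor {c!r} is constant; cannot standardize")
        y += effect * (x - x.mean()) / sd
    y += rng.normal(0.0, noise_sd, size=n)
    return df, y, tuple(active)
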