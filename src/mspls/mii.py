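"""Microstructural integrity index (MII): normative voxel-wise z-scoring.

Skeletonized diffusion metrics (FA, MD, AD, RD) from patients are compared
voxel-by-voxel against the distribution of the same voxel in a healthy
control cohort.  For metric value ``x`` of a patient at voxel ``v`` with
control mean ``m[v]`` and control standard deviation ``s[v]``, the index is
the z-score ``z[v] = (x[v] - m[v]) / s[v]``.  Averaging the z-map gives a
single global white-matter damage score per patient; averaging raw metric
values inside / outside the projected lesion mask gives the lesion and
normal-appearing white matter (NAWM) regional summaries, expressed as
percent of the control regional mean.

The control dispersion is the sample standard deviation (``ddof=1``) by
default; a population-SD variant is available through ``ddof=0``.  Voxels
whose control dispersion is zero are flagged, logged and excluded from
z-maps rather than producing infinities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    DegenerateSkeletonError,
    DimensionError,
    EmptyRegionError,
)

logger = logging.getLogger(__name__)

CONTROL = "control"
PATIENT = "patient"

#: canonical diffusion metric names, in the order used throughout the package
METRICS = ("fa", "md", "ad", "rd")


@dataclass
class SkeletonCohort:
    """Per-metric value matrices on a shared white-matter skeleton.

    Parameters
    ----------
    values
        Mapping metric name -> array of shape ``(n_subjects, n_voxels)``.
    group
        Array of ``"control"`` / ``"patient"`` labels, one per subject row.
    subject_ids
        Unique subject identifiers aligned with the rows.
    """

    values: dict[str, np.ndarray]
    group: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        shapes = {m: v.shape for m, v in self.values.items()}
        if len(set(shapes.values())) != 1:
            raise DimensionError(f"metric matrices disagree in shape: {shapes}")
        n_subjects = next(iter(shapes.values()))[0]
        if len(self.group) != n_subjects or len(self.subject_ids) != n_subjects:
            raise DimensionError(
                "group labels / subject ids do not match the subject dimension"
            )
        for m, v in self.values.items():
            if not np.all(np.isfinite(v)):
                raise DataError(f"metric {m!r} contains non-finite values")

    @property
    def metrics(self) -> tuple[str, ...]:
        return tuple(self.values)

    @property
    def n_voxels(self) -> int:
        return next(iter(self.values.values())).shape[1]

    @property
    def n_subjects(self) -> int:
        return len(self.group)

    def rows(self, group: str) -> np.ndarray:
        """Boolean row selector for ``"control"`` or ``"patient"``."""
        return np.asarray(self.group) == group

    def controls(self, metric: str) -> np.ndarray:
        return self.values[metric][self.rows(CONTROL)]

    def patients(self, metric: str) -> np.ndarray:
        return self.values[metric][self.rows(PATIENT)]

    def restrict(self, voxel_idx: np.ndarray) -> "SkeletonCohort":
        """Cohort restricted to the given voxel index set (e.g. FA-selected)."""
        return SkeletonCohort(
            values={m: v[:, voxel_idx] for m, v in self.values.items()},
            group=self.group,
            subject_ids=list(self.subject_ids),
        )


@dataclass
class ControlVoxelStats:
    """Per-voxel location/dispersion of the control distribution of one metric."""

    metric: str
    mean: np.ndarray
    sd: np.ndarray
    n_controls: int
    #: voxels with strictly positive dispersion (usable for z-scoring)
    valid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape:
            raise DimensionError("mean and sd vectors differ in length")
        self.valid = self.sd > 0

    @property
    def n_voxels(self) -> int:
        return self.mean.size


def select_skeleton_voxels(
    mean_control_fa: np.ndarray, threshold: float = 0.2
) -> np.ndarray:
    """Indices of skeleton voxels whose mean FA reaches the threshold.

    The comparison is inclusive (``>=``), matching common imaging-tool
    semantics. Raises :class:`DegenerateSkeletonError` when nothing survives.
    """
    fa = np.asarray(mean_control_fa, dtype=float)
    if not np.all(np.isfinite(fa)):
        raise DataError("mean FA vector contains non-finite values")
    idx = np.flatnonzero(fa >= threshold)
    if idx.size == 0:
        raise DegenerateSkeletonError(
            f"no voxel has mean FA >= {threshold}: skeleton is empty"
        )
    return idx


def control_voxel_stats(
    cohort: SkeletonCohort, metric: str, ddof: int = 1
) -> ControlVoxelStats:
    """Voxel-wise control mean and standard deviation for one metric.

    ``ddof=1`` (sample SD) is the default z-score denominator; ``ddof=0``
    selects the population SD. Zero-dispersion voxels are flagged on the
    returned object and a count is logged.
    """
    ctrl = cohort.controls(metric)
    if ctrl.shape[0] < 3:
        raise DataError(
            f"need >= 3 control subjects to estimate voxel statistics, got {ctrl.shape[0]}"
        )
    stats = ControlVoxelStats(
        metric=metric,
        mean=ctrl.mean(axis=0),
        sd=ctrl.std(axis=0, ddof=ddof),
        n_controls=ctrl.shape[0],
    )
    n_bad = int((~stats.valid).sum())
    if n_bad:
        logger.warning(
            "%s: %d voxel(s) with zero control dispersion excluded from z-maps",
            metric,
            n_bad,
        )
    return stats


def zscore_patient(patient_values: np.ndarray, stats: ControlVoxelStats) -> np.ndarray:
    """Voxel-wise z-map of one subject against the control distribution.

    Zero-dispersion voxels yield NaN (they are excluded downstream).
    """
    x = np.asarray(patient_values, dtype=float)
    if x.shape != stats.mean.shape:
        raise DimensionError(
            f"patient vector length {x.shape} does not match stats {stats.mean.shape}"
        )
    z = np.full(x.shape, np.nan)
    v = stats.valid
    z[v] = (x[v] - stats.mean[v]) / stats.sd[v]
    return z


def global_mii(zmap: np.ndarray, voxel_subset: np.ndarray | None = None) -> float:
    """Global white-matter damage score: mean z over a voxel subset.

    NaN entries (zero-dispersion voxels) are ignored; an empty effective
    subset raises :class:`EmptyRegionError`.
    """
    z = np.asarray(zmap, dtype=float)
    if voxel_subset is not None:
        z = z[np.asarray(voxel_subset)]
    z = z[np.isfinite(z)]
    if z.size == 0:
        raise EmptyRegionError("global MII requested over an empty voxel set")
    return float(z.mean())


def binarize_lesion_mask(soft_mask: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold an interpolated (soft) lesion mask to a binary skeleton mask.

    Values must lie in [0, 1]; the comparison is inclusive (``>=``), so the
    operation is idempotent on already-binary input.  An all-zero result is
    logged as an empty lesion set.
    """
    soft = np.asarray(soft_mask, dtype=float)
    if soft.size and (soft.min() < 0 or soft.max() > 1):
        raise DataError(
            f"soft mask values outside [0, 1]: range [{soft.min()}, {soft.max()}]"
        )
    mask = (soft >= threshold).astype(np.uint8)
    if mask.size and mask.sum() == 0:
        logger.info("lesion mask empty after thresholding at %s", threshold)
    return mask


LESION = "lesion"
NAWM = "nawm"


def regional_summary(
    cohort: SkeletonCohort,
    stats: Mapping[str, ControlVoxelStats],
    masks: np.ndarray,
    group: str = PATIENT,
) -> pd.DataFrame:
    """Lesion / NAWM regional means per subject, as percent of control.

    For each subject of ``group``, metric and region (lesion = mask 1,
    NAWM = mask 0, both restricted to valid skeleton voxels):

    ``percent_of_control = 100 * mean(subject values) / mean(control mean)``

    The mean-z variant over the same voxels is co-emitted, since the field
    reports both styles of summary.  Subjects with an empty lesion region get
    NaN lesion summaries (logged); an empty NAWM region is treated as a
    pathological mask and raises :class:`EmptyRegionError`.

    Returns a tidy frame with columns
    ``subject_id, metric, region, percent_of_control, mean_z, n_voxels``.
    """
    masks = np.asarray(masks)
    if not np.isin(masks, (0, 1)).all():
        raise DataError("lesion masks must be binary; run binarize_lesion_mask first")
    sel = cohort.rows(group)
    ids = [s for s, keep in zip(cohort.subject_ids, sel) if keep]
    if masks.shape != (len(ids), cohort.n_voxels):
        raise DimensionError(
            f"masks shape {masks.shape} does not match ({len(ids)}, {cohort.n_voxels})"
        )
    rows = []
    for metric in cohort.metrics:
        st = stats[metric]
        vals = cohort.values[metric][sel]
        for i, sid in enumerate(ids):
            lesion_v = (masks[i] == 1) & st.valid
            nawm_v = (masks[i] == 0) & st.valid
            if not nawm_v.any():
                raise EmptyRegionError(
                    f"subject {sid}: NAWM region empty (pathological mask)"
                )
            for region, vox in ((LESION, lesion_v), (NAWM, nawm_v)):
                if vox.any():
                    pct = 100.0 * vals[i, vox].mean() / st.mean[vox].mean()
                    mz = float(
                        ((vals[i, vox] - st.mean[vox]) / st.sd[vox]).mean()
                    )
                else:
                    logger.info("subject %s: empty %s region, summary missing", sid, region)
                    pct, mz = np.nan, np.nan
                rows.append(
                    {
                        "subject_id": sid,
                        "metric": metric,
                        "region": region,
                        "percent_of_control": pct,
                        "mean_z": mz,
                        "n_voxels": int(vox.sum()),
                    }
                )
    return pd.DataFrame(rows)


def global_mii_table(
    cohort: SkeletonCohort,
    stats: Mapping[str, ControlVoxelStats],
    group: str = PATIENT,
) -> pd.DataFrame:
    """Global MII (mean z over the whole skeleton) per subject and metric."""
    sel = cohort.rows(group)
    ids = [s for s, keep in zip(cohort.subject_ids, sel) if keep]
    rows = []
    for metric in cohort.metrics:
        st = stats[metric]
        for i, sid in enumerate(ids):
            z = zscore_patient(cohort.values[metric][sel][i], st)
            rows.append({"subject_id": sid, "metric": metric, "global_mii": global_mii(z)})
    return pd.DataFrame(rows)
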