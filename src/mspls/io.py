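"""Readers and writers: TSV tables, NIfTI voxel carriers, JSON reports.

TSV is the canonical tabular format (CSV is accepted on read via delimiter
sniffing).  Voxel matrices travel either as flat TSV (rows = subjects,
columns = voxel ids) or as 4D NIfTI with shape ``(1, 1, n_voxels,
n_subjects)``; the affine is recorded but unused since all statistics are
voxel-wise.  All writers round-trip at double precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import DataError, DimensionError, SchemaError
from .mii import CONTROL, PATIENT, SkeletonCohort

FLOAT_FMT = "%.17g"  # lossless for IEEE doubles


# ---------------------------------------------------------------- tables


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table (TSV or CSV; delimiter sniffed) and validate ids."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"feature table not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python")
    if "subject_id" not in df.columns:
        raise SchemaError(f"{path}: missing subject_id column")
    df["subject_id"] = df["subject_id"].astype(str)
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise SchemaError(f"{path}: duplicate subject id(s): {sorted(set(dup))}")
    for c in df.columns:
        if c == "subject_id":
            continue
        if not pd.api.types.is_numeric_dtype(df[c]):
            bad = df[c][pd.to_numeric(df[c], errors="coerce").isna()]
            raise DataError(
                f"{path}: non-numeric cells in column {c!r}: {bad.head().tolist()}"
            )
    return df


def write_feature_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


# ------------------------------------------------------- voxel matrices


def write_skeleton_tsv(cohort: SkeletonCohort, directory: str | Path) -> dict[str, Path]:
    """One TSV per metric: subject_id, group, then one column per voxel."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    voxel_cols = [f"v{j}" for j in range(cohort.n_voxels)]
    for m in cohort.metrics:
        df = pd.DataFrame(cohort.values[m], columns=voxel_cols)
        df.insert(0, "group", cohort.group)
        df.insert(0, "subject_id", cohort.subject_ids)
        p = directory / f"skeleton_{m}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format=FLOAT_FMT)
        paths[m] = p
    return paths


def read_skeleton_tsv(paths: Mapping[str, str | Path]) -> SkeletonCohort:
    values = {}
    group = subject_ids = None
    for m, p in paths.items():
        df = pd.read_csv(p, sep="\t", float_precision="round_trip")
        g = df["group"].to_numpy()
        ids = df["subject_id"].astype(str).tolist()
        if group is None:
            group, subject_ids = g, ids
        elif not (np.array_equal(group, g) and subject_ids == ids):
            raise DataError(f"{p}: subject rows disagree with other metrics")
        values[m] = df.drop(columns=["subject_id", "group"]).to_numpy(dtype=float)
    return SkeletonCohort(values=values, group=group, subject_ids=subject_ids)


def write_skeleton_nifti(
    cohort: SkeletonCohort, directory: str | Path
) -> dict[str, Path]:
    """4D NIfTI per metric with shape (1, 1, n_voxels, n_subjects)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for m in cohort.metrics:
        data = cohort.values[m].T.reshape(1, 1, cohort.n_voxels, cohort.n_subjects)
        img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.eye(4))
        p = directory / f"skeleton_{m}.nii"
        nib.save(img, str(p))
        paths[m] = p
    # subject order/groups cannot live in NIfTI; carried in a sidecar
    sidecar = directory / "subjects.tsv"
    pd.DataFrame({"subject_id": cohort.subject_ids, "group": cohort.group}).to_csv(
        sidecar, sep="\t", index=False
    )
    return paths


def read_skeleton_nifti(
    paths: Mapping[str, str | Path], sidecar: str | Path
) -> SkeletonCohort:
    side = pd.read_csv(sidecar, sep="\t")
    group = side["group"].to_numpy()
    ids = side["subject_id"].astype(str).tolist()
    values = {}
    shape = None
    for m, p in paths.items():
        p = Path(p)
        if not p.exists():
            raise DataError(f"skeleton image not found: {p}")
        img = nib.load(str(p))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if shape is None:
            shape = data.shape
        elif data.shape != shape:
            raise DimensionError(
                f"{p}: grid {data.shape} does not match {shape} of other metrics"
            )
        n_vox = int(np.prod(data.shape[:3]))
        values[m] = data.reshape(n_vox, data.shape[3]).T
    return SkeletonCohort(values=values, group=group, subject_ids=ids)


def write_masks_tsv(masks: np.ndarray, patient_ids: Sequence[str], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        np.asarray(masks), columns=[f"v{j}" for j in range(np.asarray(masks).shape[1])]
    )
    df.insert(0, "subject_id", list(patient_ids))
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def read_masks_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    ids = df["subject_id"].astype(str).tolist()
    return df.drop(columns="subject_id").to_numpy(dtype=float), ids


# ----------------------------------------------------------- JSON / YAML


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def read_config(path: str | Path) -> dict:
    """Structured key/value run configuration (YAML)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"config file not found: {path}")
    loaded = yaml.safe_load(path.read_text()) or {}
    if not isinstance(loaded, dict):
        raise DataError(f"config file {path} must contain a mapping")
    return loaded
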