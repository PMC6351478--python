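"""End-to-end analysis: predictor matrix assembly, per-outcome PLS, impairment.

The predictor set is the study's 26-column multiparametric MRI feature
vector per patient: two demographics (age, gender), three head-size
normalized global volumes (partial brain, gray matter, white matter),
twelve subcortical structure volumes (left/right amygdala, caudate,
hippocampus, pallidum, putamen, thalamus), total lesion load, and eight
diffusion summaries (FA/MD/AD/RD in the NAWM and in the lesions, as percent
of the control regional mean).  One PLS1 analysis is run per outcome:
clinical disability (EDSS) and the three BICAMS raw scores (BVMT-R,
CVLT-II, SDMT).

Cognitive impairment on a BICAMS subtest is called when a patient's score
deviates from the normative mean by strictly more than two normative SDs in
the adverse direction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import pls
from .errors import DataError, ParameterError, SchemaError

SUBCORTICAL_STRUCTURES = (
    "amygdala",
    "caudate",
    "hippocampus",
    "pallidum",
    "putamen",
    "thalamus",
)

#: canonical predictor column order (26 columns)
PREDICTOR_COLUMNS: tuple[str, ...] = (
    ("age", "gender", "pbv", "gm_volume", "wm_volume")
    + tuple(
        f"{side}_{s}" for s in SUBCORTICAL_STRUCTURES for side in ("left", "right")
    )
    + ("lesion_load",)
    + tuple(f"nawm_{m}" for m in ("fa", "md", "ad", "rd"))
    + tuple(f"lesion_{m}" for m in ("fa", "md", "ad", "rd"))
)

OUTCOME_COLUMNS: tuple[str, ...] = ("edss", "bvmt", "cvlt", "sdmt")
COGNITIVE_OUTCOMES: tuple[str, ...] = ("bvmt", "cvlt", "sdmt")

ID_COLUMN = "subject_id"


def validate_features(features: pd.DataFrame, require_outcomes: bool = False) -> pd.DataFrame:
    """Schema-check a feature table: columns, uniqueness, numeric, complete."""
    missing = [c for c in PREDICTOR_COLUMNS if c not in features.columns]
    if missing:
        raise SchemaError(f"feature table missing predictor column(s): {missing}")
    if require_outcomes:
        missing_y = [c for c in OUTCOME_COLUMNS if c not in features.columns]
        if missing_y:
            raise SchemaError(f"feature table missing outcome column(s): {missing_y}")
    if ID_COLUMN in features.columns:
        dup = features[ID_COLUMN][features[ID_COLUMN].duplicated()]
        if len(dup):
            raise SchemaError(f"duplicate subject id(s): {sorted(set(dup))}")
    block = features[list(PREDICTOR_COLUMNS)]
    bad = block.columns[~block.apply(
        lambda c: pd.api.types.is_numeric_dtype(c)
    )].tolist()
    if bad:
        raise SchemaError(f"non-numeric predictor column(s): {bad}")
    if block.isna().any().any():
        cells = [
            (str(features[ID_COLUMN].iloc[i]) if ID_COLUMN in features.columns else i, c)
            for i, c in zip(*np.where(block.isna()))
            for c in [block.columns[c]]
        ]
        raise DataError(f"missing predictor cells (subject, column): {cells}")
    return features


def build_predictor_matrix(features: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """The n x 26 predictor matrix in canonical column order.

    Input column order is irrelevant; columns are selected by name.
    """
    validate_features(features)
    X = features[list(PREDICTOR_COLUMNS)].to_numpy(dtype=float)
    return X, list(PREDICTOR_COLUMNS)


@dataclass
class AnalysisSettings:
    """Settings for the per-outcome PLS analyses."""

    n_perm: int = 5000
    seed: int = 0
    max_components: int = 2
    y_var_threshold: float = 0.10
    alpha: float = 0.05
    outcomes: tuple[str, ...] = OUTCOME_COLUMNS

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _outcome_seed(base_seed: int, k: int) -> int:
    """Stable per-outcome child seed below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), int(k)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_analysis(
    features: pd.DataFrame, settings: AnalysisSettings | None = None
) -> dict:
    """Run one PLS analysis per outcome and assemble the report.

    Per outcome: standardize -> fit PLS1 -> permutation test -> latent
    variable retention -> VIP on the retained components -> greater-than-one
    variable selection.  Deterministic under a fixed seed.
    """
    settings = settings or AnalysisSettings()
    validate_features(features, require_outcomes=False)
    if len(features) < 10:
        raise DataError(f"need >= 10 subjects for analysis, got {len(features)}")
    X, names = build_predictor_matrix(features)
    report: dict = {
        "metadata": {
            "n_subjects": int(len(features)),
            "n_predictors": len(names),
            "seed": int(settings.seed),
            "n_perm": int(settings.n_perm),
            "max_components": int(settings.max_components),
            "y_var_threshold": settings.y_var_threshold,
            "alpha": settings.alpha,
            "config_hash": settings.config_hash(),
        },
        "outcomes": {},
    }
    for k, outcome in enumerate(settings.outcomes):
        if outcome not in features.columns:
            raise SchemaError(f"outcome column {outcome!r} not in feature table")
        try:
            y = features[outcome].to_numpy(dtype=float)
            if np.isnan(y).any():
                raise DataError(f"missing cells in outcome {outcome!r}")
            Xs, ys, _ = pls.standardize(X, y, names=names)
            rank = np.linalg.matrix_rank(Xs)
            r = min(settings.max_components, int(rank))
            model = pls.fit_pls1(Xs, ys, r, predictor_names=names)
            perm = pls.permutation_test(
                Xs, ys, r,
                n_perm=settings.n_perm,
                seed=_outcome_seed(settings.seed, k),
            )
            sel = pls.select_components(
                model.ss_y, perm,
                y_var_threshold=settings.y_var_threshold,
                alpha=settings.alpha,
            )
            vip_model = model.truncate(max(sel.n_retained, 1))
            vip = pls.vip_scores(vip_model)
            report["outcomes"][outcome] = {
                "n_components_tested": r,
                "retained_components": sel.n_retained,
                "significant": bool(sel.significant),
                "ss_y": [float(v) for v in model.ss_y],
                "ss_x": [float(v) for v in model.ss_x],
                "observed_singular_values": [float(v) for v in perm.observed],
                "p_values": [float(v) for v in perm.p_values],
                "permutation_seed": perm.seed,
                "vip": [
                    {"predictor": n, "vip": float(v), "selected": bool(s)}
                    for n, v, s in zip(vip.predictor_names, vip.vip, vip.selected)
                ],
                "selected_predictors": pls.select_variables(vip),
            }
        except Exception as exc:
            raise type(exc)(f"outcome {outcome!r}: {exc}") from exc
    return report


def classify_impairment(
    score: float, norm_mean: float, norm_sd: float, direction: str = "lower"
) -> tuple[bool, float]:
    """Normative 2-SD impairment rule for one test score.

    ``direction`` names the adverse direction ("lower" for scores where less
    is worse, e.g. all BICAMS subtests).  The rule is strict: a deviation of
    exactly 2 SD is not impairment.
    Returns ``(impaired, z)``.
    """
    if norm_sd <= 0:
        raise ParameterError(f"norm_sd must be positive, got {norm_sd}")
    if direction not in ("lower", "higher"):
        raise ParameterError(f"direction must be 'lower' or 'higher', got {direction!r}")
    z = (score - norm_mean) / norm_sd
    impaired = z < -2.0 if direction == "lower" else z > 2.0
    return bool(impaired), float(z)


def summarize_impairment(flags: pd.DataFrame) -> dict[int, int]:
    """Counts of patients impaired on exactly 0, 1, 2 and 3 BICAMS subtests."""
    missing = [c for c in COGNITIVE_OUTCOMES if c not in flags.columns]
    if missing:
        raise SchemaError(f"impairment flags missing column(s): {missing}")
    per_patient = flags[list(COGNITIVE_OUTCOMES)].astype(bool).sum(axis=1)
    return {k: int((per_patient == k).sum()) for k in range(4)}


def report_text(report: dict) -> str:
    """Human-readable rendering of an analysis report."""
    lines = []
    meta = report["metadata"]
    lines.append(
        f"PLS analysis of {meta['n_subjects']} patients, "
        f"{meta['n_predictors']} predictors "
        f"(seed {meta['seed']}, {meta['n_perm']} permutations)"
    )
    for outcome, block in report["outcomes"].items():
        lines.append("")
        lines.append(f"Outcome: {outcome.upper()}")
        if not block["significant"]:
            lines.append("  no significant latent variable")
            continue
        k = block["retained_components"]
        lines.append(f"  retained latent variables: {k}")
        for a in range(block["n_components_tested"]):
            lines.append(
                f"    LV{a + 1}: {100 * block['ss_y'][a]:.2f}% of outcome variance, "
                f"{100 * block['ss_x'][a]:.2f}% of predictors, "
                f"p = {block['p_values'][a]:.4g}"
            )
        sel = sorted(
            (v for v in block["vip"] if v["selected"]),
            key=lambda v: -v["vip"],
        )
        lines.append("  predictors with VIP > 1:")
        for v in sel:
            lines.append(f"    {v['predictor']}: VIP = {v['vip']:.3f}")
    return "\n".join(lines) + "\n"
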