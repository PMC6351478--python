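"""Univariate-outcome partial least squares (PLS1) with permutation inference.

PLS decomposes standardized predictors ``X`` (n x p) and outcome ``y`` as

    X = T P' + E,      y = T q' + F,

extracting latent variables whose scores maximize covariance with the
outcome.  The implementation is NIPALS with X-deflation only, which for a
univariate outcome coincides in fitted subspace with SIMPLS.  Per component
``a``:

    w_a = X_a' y_a / ||X_a' y_a||        (unit-norm weight)
    t_a = X_a w_a                        (X score)
    p_a = X_a' t_a / (t_a' t_a)          (X loading)
    q_a = y_a' t_a / (t_a' t_a)          (y loading)
    X_{a+1} = X_a - t_a p_a',  y_{a+1} = y_a - t_a q_a

Inference on each latent variable uses a permutation null of the leading
singular value of the deflated cross-covariance (for univariate y this is
``||X_a' y_a||``): the outcome is randomly permuted, the decomposition
re-fit, and the statistic recomputed; the p-value uses the add-one rule.

Variable selection uses the Variable Importance in the Projection score

    VIP_j = sqrt( p * sum_a ssY_a w_ja^2 / sum_a ssY_a ),

whose squared values average exactly 1 over the p predictors, so predictors
with VIP > 1 (strictly) are called important ("greater-than-one" rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DataError,
    DegenerateOutcomeError,
    DimensionError,
    RankError,
)

__all__ = [
    "Scaler",
    "PLSModel",
    "PermutationResult",
    "VIPResult",
    "ComponentSelection",
    "standardize",
    "fit_pls1",
    "permutation_test",
    "vip_scores",
    "select_components",
    "select_variables",
]


@dataclass
class Scaler:
    """Column means/SDs used for standardization, kept for inverse transforms."""

    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float  # 1.0 when y is centered but not scaled

    def inverse_y(self, ys: np.ndarray) -> np.ndarray:
        return ys * self.y_sd + self.y_mean


def standardize(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    scale_y: bool = False,
) -> tuple[np.ndarray, np.ndarray, Scaler]:
    """Standardize predictor columns (mean 0, sample SD 1) and center y.

    Standardization is essential here because the predictors mix mm^3
    volumes, years, a binary indicator and percent-of-control summaries;
    without it the VIP ranking would be scale-driven.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise DataError(f"X shape {X.shape} incompatible with y length {y.size}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise DataError("standardize: input contains missing or non-finite values")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        j = int(np.flatnonzero(sd == 0)[0])
        label = names[j] if names is not None else f"column {j}"
        raise DataError(f"constant predictor column: {label}")
    mean = X.mean(axis=0)
    Xs = (X - mean) / sd
    y_mean = float(y.mean())
    y_sd = float(y.std(ddof=1)) if scale_y else 1.0
    if scale_y and y_sd == 0:
        raise DegenerateOutcomeError("outcome is constant")
    ys = (y - y_mean) / y_sd
    return Xs, ys, Scaler(mean, sd, y_mean, y_sd)


@dataclass
class PLSModel:
    """Fitted PLS1 decomposition.

    ``ss_y[a]`` / ``ss_x[a]`` are the fractions of the (centered) outcome /
    predictor sum of squares captured by component ``a``.
    """

    W: np.ndarray  # p x r unit-norm weights
    T: np.ndarray  # n x r X scores
    P: np.ndarray  # p x r X loadings
    Q: np.ndarray  # r   y loadings
    U: np.ndarray  # n x r y scores (deflated y entering each component)
    E: np.ndarray  # n x p X residual
    F: np.ndarray  # n   y residual
    ss_y: np.ndarray
    ss_x: np.ndarray
    n: int
    p: int
    r: int
    predictor_names: list[str] | None = None

    def fitted(self) -> np.ndarray:
        """Fitted (standardized-scale) outcome values, T q."""
        return self.T @ self.Q

    def truncate(self, r: int) -> "PLSModel":
        """Model restricted to the first ``r`` components.

        NIPALS extracts components sequentially, so truncation equals
        re-fitting with fewer components (residuals are recomputed).
        """
        if not 1 <= r <= self.r:
            raise RankError(f"cannot truncate to {r} of {self.r} components")
        if r == self.r:
            return self
        T, P, Q = self.T[:, :r], self.P[:, :r], self.Q[:r]
        X = self.E + self.T @ self.P.T
        y = self.F + self.T @ self.Q
        return PLSModel(
            W=self.W[:, :r],
            T=T,
            P=P,
            Q=Q,
            U=self.U[:, :r],
            E=X - T @ P.T,
            F=y - T @ Q,
            ss_y=self.ss_y[:r],
            ss_x=self.ss_x[:r],
            n=self.n,
            p=self.p,
            r=r,
            predictor_names=self.predictor_names,
        )


def _fix_sign(w: np.ndarray) -> np.ndarray:
    """Make the first non-negligible weight entry positive (reproducibility)."""
    nz = np.flatnonzero(np.abs(w) > 1e-12 * np.linalg.norm(w))
    if nz.size and w[nz[0]] < 0:
        return -w
    return w


def fit_pls1(
    Xs: np.ndarray,
    ys: np.ndarray,
    r: int,
    predictor_names: Sequence[str] | None = None,
) -> PLSModel:
    """Fit a PLS1 model with ``r`` components by NIPALS (X-deflation only)."""
    Xs = np.asarray(Xs, dtype=float)
    ys = np.asarray(ys, dtype=float).ravel()
    n, p = Xs.shape
    if n < 3:
        raise DataError(f"need at least 3 observations, got {n}")
    if not (np.all(np.isfinite(Xs)) and np.all(np.isfinite(ys))):
        raise DataError("fit_pls1: non-finite input")
    rank = np.linalg.matrix_rank(Xs)
    if not 1 <= r <= rank:
        raise RankError(f"requested {r} components but rank(X) = {rank}")
    ss_y_tot = float(ys @ ys)
    ss_x_tot = float((Xs * Xs).sum())
    if ss_y_tot == 0:
        raise DegenerateOutcomeError("outcome has zero sum of squares")

    X, y = Xs.copy(), ys.copy()
    W = np.zeros((p, r))
    T = np.zeros((n, r))
    P = np.zeros((p, r))
    Q = np.zeros(r)
    U = np.zeros((n, r))
    ss_y = np.zeros(r)
    ss_x = np.zeros(r)
    for a in range(r):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm <= 1e-14 * max(1.0, np.abs(X).max()):
            raise RankError(
                f"cross-covariance exhausted after {a} components; reduce r"
            )
        w = _fix_sign(w / norm)
        t = X @ w
        tt = float(t @ t)
        if tt <= 0:
            raise RankError(f"degenerate score at component {a + 1}")
        pa = X.T @ t / tt
        qa = float(y @ t) / tt
        W[:, a], T[:, a], P[:, a], Q[a] = w, t, pa, qa
        U[:, a] = y
        ss_y[a] = qa * qa * tt / ss_y_tot
        ss_x[a] = float(pa @ pa) * tt / ss_x_tot
        X = X - np.outer(t, pa)
        y = y - t * qa
    return PLSModel(
        W=W,
        T=T,
        P=P,
        Q=Q,
        U=U,
        E=X,
        F=y,
        ss_y=ss_y,
        ss_x=ss_x,
        n=n,
        p=p,
        r=r,
        predictor_names=list(predictor_names) if predictor_names is not None else None,
    )


def _cross_covariance_path(X: np.ndarray, y: np.ndarray, r: int) -> np.ndarray:
    """Leading cross-covariance singular value per component, with deflation.

    For univariate y the leading singular value of ``X_a' y_a`` is simply its
    Euclidean norm.  Components past an exhausted covariance report 0.
    """
    X = X.copy()
    y = y.copy()
    out = np.zeros(r)
    for a in range(r):
        w = X.T @ y
        s = float(np.linalg.norm(w))
        out[a] = s
        if s <= 0:
            break
        w /= s
        t = X @ w
        tt = float(t @ t)
        if tt <= 0:
            break
        pa = X.T @ t / tt
        qa = float(y @ t) / tt
        X -= np.outer(t, pa)
        y -= t * qa
    return out


@dataclass
class PermutationResult:
    """Permutation null of the per-component cross-covariance singular value."""

    observed: np.ndarray  # r
    null: np.ndarray  # n_perm x r
    p_values: np.ndarray  # r, add-one rule
    n_perm: int
    seed: int


def permutation_test(
    Xs: np.ndarray,
    ys: np.ndarray,
    r: int,
    n_perm: int = 5000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of each latent variable's singular value.

    The outcome vector is randomly permuted ``n_perm`` times (fresh
    permutation per draw; the design matrix stays fixed), the decomposition
    is re-fit on the permuted data, and the per-component statistic is
    recomputed to build the null.  p-values use the add-one rule
    ``p = (1 + #{null >= observed}) / (1 + n_perm)`` so they are never zero.
    """
    if n_perm < 1:
        raise ConfigurationError(f"n_perm must be >= 1, got {n_perm}")
    Xs = np.asarray(Xs, dtype=float)
    ys = np.asarray(ys, dtype=float).ravel()
    if np.all(ys == ys[0]):
        raise DegenerateOutcomeError("outcome is constant; permutation null undefined")
    observed = _cross_covariance_path(Xs, ys, r)
    rng = np.random.default_rng(seed)
    null = np.zeros((n_perm, r))
    for b in range(n_perm):
        null[b] = _cross_covariance_path(Xs, rng.permutation(ys), r)
    p_values = (1 + (null >= observed).sum(axis=0)) / (1 + n_perm)
    return PermutationResult(
        observed=observed, null=null, p_values=p_values, n_perm=n_perm, seed=seed
    )


@dataclass
class VIPResult:
    """Per-predictor VIP scores and greater-than-one selection flags."""

    vip: np.ndarray
    selected: np.ndarray
    predictor_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": self.predictor_names,
                "vip": self.vip,
                "selected": self.selected,
            }
        )


def vip_scores(model: PLSModel) -> VIPResult:
    """Variable Importance in the Projection for every predictor.

    Weighted by each component's share of explained outcome variance; the
    mean of the squared scores equals 1 by construction (unit-norm weights).
    """
    total = float(model.ss_y.sum())
    if total <= 0:
        raise DegenerateOutcomeError("all components explain zero outcome variance")
    vip = np.sqrt(model.p * (model.W**2) @ model.ss_y / total)
    names = model.predictor_names or [f"x{j}" for j in range(model.p)]
    return VIPResult(vip=vip, selected=vip > 1.0, predictor_names=list(names))


@dataclass
class ComponentSelection:
    """Outcome of the latent-variable retention rule."""

    n_retained: int
    significant: bool  # False when even the first component fails significance


def select_components(
    ss_y: np.ndarray,
    perm: PermutationResult,
    y_var_threshold: float = 0.10,
    alpha: float = 0.05,
) -> ComponentSelection:
    """Retain leading components that are both significant and substantial.

    Keeps the largest prefix of components with permutation p <= ``alpha``
    and explained-outcome-variance fraction >= ``y_var_threshold``.  The
    first component is retained on significance alone; if it is not
    significant there is no model to interpret.
    """
    ss_y = np.asarray(ss_y, dtype=float)
    p_values = np.asarray(perm.p_values, dtype=float)
    if ss_y.shape != p_values.shape:
        raise DimensionError(
            f"ss_y shape {ss_y.shape} does not match p-values shape {p_values.shape}"
        )
    if p_values[0] > alpha:
        return ComponentSelection(n_retained=0, significant=False)
    retained = 1
    for a in range(1, ss_y.size):
        if p_values[a] <= alpha and ss_y[a] >= y_var_threshold:
            retained = a + 1
        else:
            break
    return ComponentSelection(n_retained=retained, significant=True)


def select_variables(vip: VIPResult) -> list[str]:
    """Names of predictors passing the strict greater-than-one VIP rule."""
    return [n for n, v in zip(vip.predictor_names, vip.vip) if v > 1.0]
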