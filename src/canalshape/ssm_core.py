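"""Point-distribution shape model of the canal.

Each corresponded shape (30 sections × 50 points) is standardized — centroid
at the origin, isotropic scale so the longitudinal (z) extent spans 1 — and
flattened to a 4500-vector (section-major, point-minor, xyz).  PCA of the
cohort matrix yields the mean shape, orthonormal modes and their variances;
shapes are synthesized as mean + sum_i c_i · sqrt(lambda_i) · v_i with the
coefficients in SD units.

Standardization is deliberately NOT per-variable unit-variance scaling: that
would destroy the shape semantics of the coordinates.  The z-normalization
suppresses a global size mode, so the leading components are shape, not size.

PCA is computed via SVD of the centered matrix (numerically equivalent to an
eigen-decomposition of the sample covariance with divisor n−1, and stable for
4500 columns).  Eigenvector signs are fixed so the largest-magnitude entry of
each mode is positive, making synthesized figures reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contour_io import AlignedShape

__all__ = [
    "ShapeMatrix",
    "SSMModel",
    "standardize_shape",
    "build_shape_matrix",
    "fit_ssm",
    "project",
    "synthesize",
    "explained_variance",
    "save_model",
    "load_model",
]


@dataclass
class ShapeMatrix:
    """n_specimens × 4500 matrix of standardized coordinates, rows = ids."""

    ids: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or len(self.ids) != self.X.shape[0]:
            raise ValueError("ShapeMatrix: ids must match rows")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("ShapeMatrix: non-finite values")


@dataclass
class SSMModel:
    """PCA shape model: mean, orthonormal modes, variances, training scores."""

    mean_shape: np.ndarray  # (p,)
    components: np.ndarray  # (k, p) rows orthonormal
    eigenvalues: np.ndarray  # (k,) non-increasing variances
    scores: np.ndarray  # (n, k) training scores
    ids: list[str] = field(default_factory=list)
    n_retained: int = 3

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def standardize_shape(shape: AlignedShape) -> np.ndarray:
    """Standardized 4500-vector: centroid at origin, z-extent scaled to 1,
    flattened section-major / point-minor / xyz."""
    pts = shape.sections.reshape(-1, 3).astype(float)
    pts = pts - pts.mean(axis=0)
    extent = pts[:, 2].max() - pts[:, 2].min()
    if extent <= 0:
        raise ValueError("standardize_shape: zero longitudinal extent")
    return (pts / extent).ravel()


def build_shape_matrix(shapes: list[AlignedShape]) -> ShapeMatrix:
    return ShapeMatrix(
        ids=[s.meta.id for s in shapes],
        X=np.stack([standardize_shape(s) for s in shapes]),
    )


def fit_ssm(matrix: ShapeMatrix, n_retained: int = 3) -> SSMModel:
    """PCA of the shape matrix via SVD of the centered data.

    Keeps min(n−1, p) components; eigenvalues are sample variances (divisor
    n−1) sorted non-increasing, and their sum equals the total variance of
    the matrix.
    """
    X = matrix.X
    n, p = X.shape
    if n < 2:
        raise ValueError("fit_ssm needs >= 2 specimens")
    mean = X.mean(axis=0)
    Xc = X - mean
    k = min(n - 1, p)
    if p > 4 * n:
        # few specimens, many coordinates: eigen-decompose the n x n Gram
        # matrix instead of the p x p covariance (same spectrum, much faster)
        w, U = np.linalg.eigh(Xc @ Xc.T)
        order = np.argsort(w)[::-1][:k]
        w = np.clip(w[order], 0.0, None)
        S = np.sqrt(w)
        with np.errstate(divide="ignore", invalid="ignore"):
            Vt = np.where(S[:, None] > 0, (Xc.T @ U[:, order]).T / S[:, None], 0.0)
    else:
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        S, Vt = S[:k], Vt[:k]
    eigenvalues = S**2 / (n - 1)
    # deterministic sign: largest-|entry| of each mode positive
    flip = np.sign(Vt[np.arange(k), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    scores = Xc @ Vt.T
    return SSMModel(
        mean_shape=mean,
        components=Vt,
        eigenvalues=eigenvalues,
        scores=scores,
        ids=list(matrix.ids),
        n_retained=min(n_retained, k),
    )


def project(model: SSMModel, shape_vec: np.ndarray) -> np.ndarray:
    """PC scores of a standardized shape vector: v_i · (x − mean)."""
    x = np.asarray(shape_vec, dtype=float)
    if x.shape != model.mean_shape.shape:
        raise ValueError(
            f"dimension mismatch: {x.shape} vs model {model.mean_shape.shape}"
        )
    return model.components @ (x - model.mean_shape)


def synthesize(
    model: SSMModel, coefficients: np.ndarray, bound: float = 3.0
) -> np.ndarray:
    """Shape at the given per-component multiples of SD:
    mean + sum_i c_i sqrt(lambda_i) v_i.

    Coefficients beyond ``n_retained`` components are rejected, as are
    magnitudes above ``bound`` SD.
    """
    c = np.asarray(coefficients, dtype=float)
    if c.ndim != 1 or len(c) > model.n_retained:
        raise ValueError(
            f"coefficients address {len(c)} components; model retains "
            f"{model.n_retained}"
        )
    if np.any(np.abs(c) > bound):
        raise ValueError(f"|coefficients| exceed the {bound} SD bound")
    k = len(c)
    return model.mean_shape + (c * np.sqrt(model.eigenvalues[:k])) @ model.components[:k]


def explained_variance(model: SSMModel) -> pd.DataFrame:
    """Scree table: per-component and cumulative explained-variance fractions."""
    total = model.eigenvalues.sum()
    frac = model.eigenvalues / total if total > 0 else np.zeros_like(model.eigenvalues)
    return pd.DataFrame(
        {
            "component": np.arange(1, model.n_components + 1),
            "eigenvalue": model.eigenvalues,
            "fraction": frac,
            "cumulative": np.cumsum(frac),
        }
    )


def save_model(model: SSMModel, path: str | Path) -> None:
    """Serialize to a compressed NumPy archive with a metadata record."""
    np.savez_compressed(
        path,
        mean_shape=model.mean_shape,
        components=model.components,
        eigenvalues=model.eigenvalues,
        scores=model.scores,
        meta=json.dumps({"ids": model.ids, "n_retained": model.n_retained}),
    )


def load_model(path: str | Path) -> SSMModel:
    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["meta"]))
        return SSMModel(
            mean_shape=f["mean_shape"],
            components=f["components"],
            eigenvalues=f["eigenvalues"],
            scores=f["scores"],
            ids=list(meta["ids"]),
            n_retained=int(meta["n_retained"]),
        )
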