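"""Shape-model quality: specificity and generalization.

Specificity: sample synthetic shapes with coefficients drawn uniformly in
[−2, +2] SD along the retained components, and compare each sample's nearest-
neighbor Euclidean distance to the training set against the real-to-real
(leave-one-out) nearest-neighbor baseline.  A specific model produces few
samples beyond the real 95th percentile.

Generalization: 10-fold cross-validation — fit on 90% of shapes, project the
held-out 10% onto the retained components, reconstruct, and record the scaled
mean squared error (squared residual norm / number of coordinates, a
per-coordinate variance-like quantity in standardized space).  A model that
generalizes shows held-out errors indistinguishable from training errors.

Distances are full Euclidean norms of 4500-vector differences; percentiles
use linear interpolation (NumPy default).  Reports are reproducible from
(cohort, seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import KFold

from .ssm_core import ShapeMatrix, SSMModel, fit_ssm

__all__ = [
    "SpecificityReport",
    "GeneralizationReport",
    "sample_shapes",
    "specificity",
    "crossval_generalization",
]


@dataclass
class SpecificityReport:
    synth_nn_distances: np.ndarray
    real_nn_distances: np.ndarray
    synth_mean: float
    synth_sd: float
    synth_median: float
    real_mean: float
    real_sd: float
    real_median: float
    real_p95: float
    frac_exceeding_p95: float
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "synth_mean": self.synth_mean,
            "synth_sd": self.synth_sd,
            "synth_median": self.synth_median,
            "real_mean": self.real_mean,
            "real_sd": self.real_sd,
            "real_median": self.real_median,
            "real_p95": self.real_p95,
            "frac_exceeding_p95": self.frac_exceeding_p95,
            "n_samples": int(len(self.synth_nn_distances)),
            "n_real": int(len(self.real_nn_distances)),
            "seed": self.seed,
        }


@dataclass
class GeneralizationReport:
    train_mse: np.ndarray  # per fold
    test_mse: np.ndarray
    fold_assignment: np.ndarray  # fold index per specimen
    seed: int | None = None

    @property
    def train_mean(self) -> float:
        return float(self.train_mse.mean())

    @property
    def test_mean(self) -> float:
        return float(self.test_mse.mean())

    def to_dict(self) -> dict:
        return {
            "train_mean": self.train_mean,
            "train_sd": float(self.train_mse.std(ddof=1)),
            "train_median": float(np.median(self.train_mse)),
            "test_mean": self.test_mean,
            "test_sd": float(self.test_mse.std(ddof=1)),
            "test_median": float(np.median(self.test_mse)),
            "n_folds": int(len(self.train_mse)),
            "seed": self.seed,
        }


def sample_shapes(
    model: SSMModel,
    n_samples: int,
    bound_sd: float = 2.0,
    n_components: int = 3,
    seed: int | None = None,
) -> np.ndarray:
    """Synthetic shapes with coefficients uniform in [−bound_sd, bound_sd] SD
    along the first ``n_components`` modes (others zero).  Reproducible from
    ``seed``; returns an (n_samples, p) array."""
    if n_components > model.n_components:
        raise ValueError(
            f"n_components={n_components} exceeds available {model.n_components}"
        )
    rng = np.random.default_rng(seed)
    coeffs = rng.uniform(-bound_sd, bound_sd, size=(n_samples, n_components))
    sd = np.sqrt(model.eigenvalues[:n_components])
    return model.mean_shape + (coeffs * sd) @ model.components[:n_components]


def specificity(
    model: SSMModel,
    matrix: ShapeMatrix,
    samples: np.ndarray,
    seed: int | None = None,
) -> SpecificityReport:
    """Nearest-neighbor specificity of sampled shapes against the cohort."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] == 0:
        raise ValueError("specificity needs at least one sample")
    X = matrix.X
    if X.shape[0] < 2:
        raise ValueError("specificity needs >= 2 real shapes")
    synth_nn = cdist(samples, X).min(axis=1)
    dreal = cdist(X, X)
    np.fill_diagonal(dreal, np.inf)
    real_nn = dreal.min(axis=1)
    real_p95 = float(np.percentile(real_nn, 95))
    return SpecificityReport(
        synth_nn_distances=synth_nn,
        real_nn_distances=real_nn,
        synth_mean=float(synth_nn.mean()),
        synth_sd=float(synth_nn.std(ddof=1)) if len(synth_nn) > 1 else 0.0,
        synth_median=float(np.median(synth_nn)),
        real_mean=float(real_nn.mean()),
        real_sd=float(real_nn.std(ddof=1)),
        real_median=float(np.median(real_nn)),
        real_p95=real_p95,
        frac_exceeding_p95=float(np.mean(synth_nn > real_p95)),
        seed=seed,
    )


def _scaled_mse(model: SSMModel, rows: np.ndarray, k: int) -> float:
    """Mean over shapes of squared reconstruction residual norm / p."""
    Xc = rows - model.mean_shape
    V = model.components[:k]
    resid = Xc - (Xc @ V.T) @ V
    return float(np.mean(np.sum(resid**2, axis=1)) / rows.shape[1])


def crossval_generalization(
    matrix: ShapeMatrix,
    n_folds: int = 10,
    n_retained: int = 3,
    seed: int | None = None,
) -> GeneralizationReport:
    """K-fold cross-validated reconstruction error with ``n_retained`` modes."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    n = matrix.X.shape[0]
    if n < n_folds:
        raise ValueError(f"need >= {n_folds} specimens for {n_folds}-fold CV")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    train_mse = np.empty(n_folds)
    test_mse = np.empty(n_folds)
    assignment = np.empty(n, dtype=int)
    for f, (tr, te) in enumerate(kf.split(matrix.X)):
        assignment[te] = f
        sub = ShapeMatrix(ids=[matrix.ids[i] for i in tr], X=matrix.X[tr])
        model = fit_ssm(sub, n_retained=n_retained)
        k = min(n_retained, model.n_components)
        train_mse[f] = _scaled_mse(model, matrix.X[tr], k)
        test_mse[f] = _scaled_mse(model, matrix.X[te], k)
    return GeneralizationReport(
        train_mse=train_mse, test_mse=test_mse, fold_assignment=assignment, seed=seed
    )
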