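"""Geometric features of the medullary canal.

Per section (30 per specimen): contour area A (polygonal approximation from
the ordered perimeter points), equivalent radius r_eq = sqrt(A/pi), normalized
radius r_eq/L with L the retained segment length, medullary roundness index
MRI = a/b of the direct least-squares ellipse fit, and major-axis angle phi
(degrees from +x, a per-contour torsion proxy).

Per specimen: mean r_eq/L, mean MRI, overall torsion delta_phi (unwrapped
phi_29 − phi_0), flare index max(r_eq)/min(r_eq), and curvature 1/R of the
least-squares sphere through the 30 section centroids, reported dimensionless
as L/R.

Features are computed on the aligned, unscaled shape; the isotropic z-extent
normalization happens only when assembling the shape matrix for PCA (r_eq/L
already removes size here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._polygon import area_centroid
from ._polygon import polygon_area as _poly_area
from .contour_io import AlignedShape

__all__ = [
    "EllipseFit",
    "ContourFeatureProfile",
    "FeatureSummary",
    "polygon_area",
    "equivalent_radius",
    "fit_ellipse",
    "unwrap_phi",
    "contour_profile",
    "flare_index",
    "fit_sphere",
    "summarize",
    "summaries_to_frame",
    "profile_to_frame",
]

# MRI below 1 + _ROUND_TOL counts as circular: phi is orientation-ambiguous
_ROUND_TOL = 1e-3


@dataclass(frozen=True)
class EllipseFit:
    """Geometric parameters of a fitted ellipse; a >= b, phi in [0, 180) deg."""

    center: np.ndarray
    a: float
    b: float
    phi: float
    ambiguous: bool = False  # near-circular: phi not meaningful


@dataclass
class ContourFeatureProfile:
    """Per-section features of one specimen (arrays of length n_sections)."""

    area: np.ndarray
    r_eq: np.ndarray
    r_eq_over_L: np.ndarray
    mri: np.ndarray
    phi_raw: np.ndarray
    phi_unwrapped: np.ndarray
    ambiguous: np.ndarray  # bool flags where MRI ~ 1


@dataclass(frozen=True)
class FeatureSummary:
    """Specimen-level feature summary (all dimensionless except delta_phi, deg)."""

    mean_r_eq_over_L: float
    mean_mri: float
    delta_phi: float
    flare_index: float
    curvature: float  # 1/mm
    normalized_curvature: float  # L/R


def polygon_area(points: np.ndarray) -> float:
    """Contour area by the shoelace formula (absolute value), mm^2."""
    return _poly_area(points)


def equivalent_radius(points: np.ndarray) -> float:
    """Radius of the circle with the same area as the contour, sqrt(A/pi)."""
    return float(np.sqrt(polygon_area(points) / np.pi))


def fit_ellipse(points: np.ndarray) -> EllipseFit:
    """Direct least-squares ellipse fit (numerically stable Halir–Flusser
    partitioning of the Fitzgibbon conic fit).

    Non-iterative, always returns an ellipse, and recovers noiseless ellipse
    samples exactly.  Raises on degenerate input (< 6 points or collinear).
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[0] < 6 or p.shape[1] != 2:
        raise ValueError("fit_ellipse needs >= 6 planar points")
    mean = p.mean(axis=0)
    x, y = (p - mean).T  # center for conditioning
    if np.linalg.matrix_rank(np.column_stack([x, y]), tol=1e-12 * max(1.0, np.abs(p).max())) < 2:
        raise ValueError("fit_ellipse: points are collinear")
    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"fit_ellipse: degenerate conic system ({e})") from e
    M = S1 + S2 @ T
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    w, V = np.linalg.eig(M)
    cond = 4.0 * V[0] * V[2] - V[1] ** 2
    idx = np.where(cond > 0)[0]
    if len(idx) == 0:
        raise ValueError("fit_ellipse: no elliptical solution (degenerate input)")
    a1 = np.real(V[:, idx[0]])
    coeffs = np.concatenate([a1, T @ a1])  # A,B,C,D,E,F in centered coords
    A, B, C, D, E, F = coeffs
    # ellipse center in centered coords
    den = 4.0 * A * C - B * B
    cx = (B * E - 2.0 * C * D) / den
    cy = (B * D - 2.0 * A * E) / den
    Fc = A * cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F
    Q = np.array([[A, B / 2.0], [B / 2.0, C]])
    lam, vec = np.linalg.eigh(Q)
    if np.any(lam * (-Fc) <= 0):
        raise ValueError("fit_ellipse: conic is not a real ellipse")
    semi = np.sqrt(-Fc / lam)
    order = np.argsort(semi)[::-1]  # major first
    a_len, b_len = float(semi[order[0]]), float(semi[order[1]])
    major = vec[:, order[0]]
    phi = float(np.degrees(np.arctan2(major[1], major[0]))) % 180.0
    return EllipseFit(
        center=np.array([cx, cy]) + mean,
        a=a_len,
        b=b_len,
        phi=phi,
        ambiguous=(a_len - b_len) / a_len < _ROUND_TOL,
    )


def unwrap_phi(phi_raw: np.ndarray) -> np.ndarray:
    """Unwrap a sequence of major-axis angles defined modulo 180 degrees.

    Each successive jump is brought into (−90, +90] by adding multiples of
    180; the first value is kept in [0, 180).
    """
    phi = np.asarray(phi_raw, dtype=float)
    out = np.empty_like(phi)
    out[0] = phi[0] % 180.0
    for k in range(1, len(phi)):
        d = phi[k] - out[k - 1]
        d = (d + 90.0) % 180.0 - 90.0
        out[k] = out[k - 1] + d
    return out


def contour_profile(shape: AlignedShape) -> ContourFeatureProfile:
    """Per-section area, r_eq, r_eq/L, MRI and phi for an aligned shape.

    phi is unwrapped along the stack; near-circular sections (MRI within 1e-3
    of 1) inherit the previous section's unwrapped angle (0 for section 0) and
    are flagged.
    """
    L = shape.segment_length
    n = shape.sections.shape[0]
    area = np.empty(n)
    mri = np.empty(n)
    phi_raw = np.empty(n)
    ambiguous = np.zeros(n, dtype=bool)
    for k in range(n):
        xy = shape.sections[k, :, :2]
        area[k] = polygon_area(xy)
        fit = fit_ellipse(xy)
        mri[k] = fit.a / fit.b
        phi_raw[k] = fit.phi
        ambiguous[k] = fit.ambiguous
    r_eq = np.sqrt(area / np.pi)
    phi_u = unwrap_phi(phi_raw)
    for k in np.where(ambiguous)[0]:
        phi_u[k] = phi_u[k - 1] if k > 0 else 0.0
    return ContourFeatureProfile(
        area=area,
        r_eq=r_eq,
        r_eq_over_L=r_eq / L,
        mri=mri,
        phi_raw=phi_raw,
        phi_unwrapped=phi_u,
        ambiguous=ambiguous,
    )


def flare_index(profile: ContourFeatureProfile) -> float:
    """Ratio of the largest to the smallest equivalent radius across sections."""
    return float(profile.r_eq.max() / profile.r_eq.min())


def fit_sphere(
    centroids: np.ndarray, rcond: float = 1e-8
) -> tuple[np.ndarray, float, float]:
    """Algebraic least-squares sphere through 3-D points.

    Solves the linear system [2x 2y 2z 1]·[c, R²−|c|²] = |p|² in centered
    coordinates.  A sphere through effectively coplanar points is ill-posed
    (any sphere containing the circle fits), and section centroids lie almost
    exactly on a planar arc, so a direct least-squares solution is dominated
    by out-of-plane deviations orders of magnitude below the arc geometry.
    When the out-of-plane extent is below 10% of the secondary in-plane
    extent the points are therefore projected onto their best-fit plane and
    an algebraic circle fit (Kåsa) supplies the radius, with the sphere
    center placed in that plane — the geometrically meaningful solution, and
    exact on noiseless arcs.  Otherwise the full sphere system is solved
    (``rcond`` guards residual rank deficiency), which is exact on generic
    noiseless sphere samples.

    Returns (center, R, rms_residual).  Collinear centroids (a straight
    canal) yield R = inf with zero curvature downstream.
    """
    p = np.asarray(centroids, dtype=float)
    if p.ndim != 2 or p.shape[0] < 4 or p.shape[1] != 3:
        raise ValueError("fit_sphere needs >= 4 points in 3-D")
    mean = p.mean(axis=0)
    q = p - mean  # translation-invariant formulation
    sv = np.linalg.svd(q, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):  # collinear: straight canal
        return np.full(3, np.nan), np.inf, 0.0
    if sv[2] < 0.1 * sv[1]:  # effectively planar arc: circle in its plane
        _, _, Vt = np.linalg.svd(q, full_matrices=False)
        uv = q @ Vt[:2].T
        A2 = np.column_stack([2.0 * uv, np.ones(len(uv))])
        sol2, *_ = np.linalg.lstsq(A2, np.sum(uv * uv, axis=1), rcond=None)
        r2 = sol2[2] + sol2[:2] @ sol2[:2]
        center = mean + Vt[:2].T @ sol2[:2]
    else:
        A = np.column_stack([2.0 * q, np.ones(len(q))])
        b = np.sum(q * q, axis=1)
        scale = np.linalg.norm(A, axis=0)
        sol, *_ = np.linalg.lstsq(A / scale, b, rcond=rcond)
        sol = sol / scale
        center = sol[:3]
        r2 = sol[3] + center @ center
        center = center + mean
    if r2 <= 0:
        return np.full(3, np.nan), np.inf, 0.0
    R = float(np.sqrt(r2))
    residual = float(np.sqrt(np.mean((np.linalg.norm(p - center, axis=1) - R) ** 2)))
    return center, R, residual


def summarize(shape: AlignedShape, profile: ContourFeatureProfile) -> FeatureSummary:
    """Specimen-level summary of the five canal features."""
    centroids = np.empty((shape.sections.shape[0], 3))
    for k in range(shape.sections.shape[0]):
        centroids[k, :2] = area_centroid(shape.sections[k, :, :2])
        centroids[k, 2] = shape.sections[k, 0, 2]
    _, R, _ = fit_sphere(centroids)
    curvature = 0.0 if np.isinf(R) else 1.0 / R
    L = shape.segment_length
    return FeatureSummary(
        mean_r_eq_over_L=float(profile.r_eq_over_L.mean()),
        mean_mri=float(profile.mri.mean()),
        delta_phi=float(profile.phi_unwrapped[-1] - profile.phi_unwrapped[0]),
        flare_index=flare_index(profile),
        curvature=curvature,
        normalized_curvature=0.0 if np.isinf(R) else float(L / R),
    )


FEATURE_NAMES = [
    "mean_r_eq_over_L",
    "mean_mri",
    "delta_phi",
    "flare_index",
    "normalized_curvature",
]


def summaries_to_frame(
    ids: list[str], summaries: list[FeatureSummary]
) -> pd.DataFrame:
    """One row per specimen, indexed by specimen id."""
    return pd.DataFrame(
        [
            {
                "mean_r_eq_over_L": s.mean_r_eq_over_L,
                "mean_mri": s.mean_mri,
                "delta_phi": s.delta_phi,
                "flare_index": s.flare_index,
                "curvature": s.curvature,
                "normalized_curvature": s.normalized_curvature,
            }
            for s in summaries
        ],
        index=pd.Index(ids, name="specimen_id"),
    )


def profile_to_frame(specimen_id: str, profile: ContourFeatureProfile) -> pd.DataFrame:
    """Long-form per-contour table for one specimen."""
    n = len(profile.area)
    return pd.DataFrame(
        {
            "specimen_id": specimen_id,
            "section": np.arange(n),
            "area": profile.area,
            "r_eq": profile.r_eq,
            "r_eq_over_L": profile.r_eq_over_L,
            "mri": profile.mri,
            "phi_raw": profile.phi_raw,
            "phi_unwrapped": profile.phi_unwrapped,
            "ambiguous": profile.ambiguous,
        }
    )
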