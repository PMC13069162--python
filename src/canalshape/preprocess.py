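"""Contour-stack preprocessing and point correspondence.

The pipeline standardizes each specimen before shape modeling:

1. densify the stack to 100 slices by linear blending of neighboring contours,
2. trim to the analysis window — proximally 10% of femur length distal to the
   greater trochanter (GT), retaining 22.1% of femur length,
3. mirror left femora about the sagittal plane so all canals are right-sided,
4. translate the point-cloud centroid to the origin,
5. fit a minimum-volume enclosing ellipsoid (MVEE, Khachiyan ascent) and rotate
   into its principal frame — a landmark-free orientation proxy,
6. reslice 30 uniformly spaced planar sections in the aligned frame
   (index 0 distal → 29 proximal),
7. resample each section to 50 points at equal arc length on a periodic cubic
   spline, starting at the posterior ray through the section centroid.

The result is a point-correspondent shape of 30 × 50 = 1500 points.

Conventions (fixed once; the source protocol does not state them): contours
are stored counter-clockwise viewed from proximal (+z); the posterior ray
points along −y; where the ray crosses a non-convex contour more than once,
the crossing farthest from the centroid is used.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from ._polygon import area_centroid, signed_area
from .contour_io import AlignedShape, ContourStack, SpecimenMeta, validate_stack

__all__ = [
    "Ellipsoid",
    "RotatedStack",
    "PipelineError",
    "interpolate_slices",
    "trim_canal",
    "mirror_to_right",
    "fit_mvee",
    "alignment_rotation",
    "align_to_ellipsoid",
    "reslice_sections",
    "resample_contour",
    "build_correspondence",
    "TRIM_PROXIMAL_FRAC",
    "TRIM_LENGTH_FRAC",
]

logger = logging.getLogger(__name__)

# trimming window as fractions of femur length (distal to the GT landmark)
TRIM_PROXIMAL_FRAC = 0.10
TRIM_LENGTH_FRAC = 0.221

_DENSE = 4096  # dense spline samples for arc-length tables


class PipelineError(RuntimeError):
    """A preprocessing stage failed; the message names the stage."""


@dataclass(frozen=True)
class Ellipsoid:
    """Ellipsoid (p-c)^T M (p-c) <= 1 with M = axes diag(1/r^2) axes^T.

    ``axes`` columns are the principal directions, ``radii`` the semi-axis
    lengths sorted descending.
    """

    center: np.ndarray
    axes: np.ndarray
    radii: np.ndarray

    def quadratic_form(self, points: np.ndarray) -> np.ndarray:
        """(p-c)^T M (p-c) for each point; <= 1 means inside."""
        d = (np.atleast_2d(points) - self.center) @ self.axes
        return np.sum((d / self.radii) ** 2, axis=1)


@dataclass
class RotatedStack:
    """Stack after rigid alignment: the original slices become tilted 3-D
    rings (each an (n, 3) array), ordered by mean z."""

    meta: SpecimenMeta
    rings: list[np.ndarray]


# ---------------------------------------------------------------------------
# contour resampling


def _periodic_spline(points: np.ndarray) -> tuple[CubicSpline, float]:
    """Closed cubic spline through the points, chord-length parameterized.

    Returns the spline and the period T of the parameter.
    """
    p = np.asarray(points, dtype=float)
    closed = np.vstack([p, p[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    if np.any(seg <= 0):
        raise ValueError("contour has duplicate consecutive points")
    t = np.concatenate([[0.0], np.cumsum(seg)])
    return CubicSpline(t, closed, bc_type="periodic"), float(t[-1])


def _posterior_ray_param(
    spline: CubicSpline, period: float, centroid: np.ndarray, t_dense: np.ndarray,
    xy_dense: np.ndarray,
) -> float:
    """Spline parameter where the −y ray from the centroid crosses the contour.

    For non-convex contours with several crossings the one farthest from the
    centroid along −y is chosen (stable for near-elliptical sections).
    """
    cx, cy = centroid[0], centroid[1]
    f = xy_dense[:, 0] - cx
    roots: list[float] = []
    for i in range(len(t_dense) - 1):
        a, b = f[i], f[i + 1]
        if a == 0.0:
            roots.append(float(t_dense[i]))
        elif a * b < 0:
            roots.append(
                float(
                    brentq(
                        lambda t: float(spline(t)[0]) - cx,
                        t_dense[i],
                        t_dense[i + 1],
                        xtol=1e-12 * max(period, 1.0),
                    )
                )
            )
    best_t, best_y = None, np.inf
    for t in roots:
        y = float(spline(t)[1])
        if y < cy and y < best_y:
            best_t, best_y = t, y
    if best_t is None:
        raise ValueError(
            "posterior ray from centroid does not intersect the contour "
            "(is the centroid outside?)"
        )
    return best_t


def _equal_arc_params(
    t_dense: np.ndarray, pts_dense: np.ndarray, t0: float, period: float, n: int
) -> np.ndarray:
    """Parameters of n equal-arc-length points starting at parameter t0."""
    seg = np.linalg.norm(np.diff(pts_dense[:, :2], axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])  # arc length at t_dense
    perimeter = s[-1]
    s0 = float(np.interp(t0 % period, t_dense, s))
    targets = (s0 + perimeter * np.arange(n) / n) % perimeter
    return np.interp(targets, s, t_dense)


def _resample_any(points: np.ndarray, n_pts: int, centroid=None) -> np.ndarray:
    """Resample a closed contour (2-D or 3-D ring) to n_pts equal-arc points.

    Orientation is normalized to counter-clockwise in the xy projection; the
    start point is the posterior-ray crossing.  Arc length is measured in the
    xy projection so planar and gently tilted rings share one parameterization.
    """
    p = np.asarray(points, dtype=float)
    if p.shape[0] < 8:
        raise ValueError(f"contour has {p.shape[0]} points; need >= 8")
    if signed_area(p[:, :2]) < 0:
        p = p[::-1]
    if centroid is None:
        centroid = area_centroid(p[:, :2])
    spline, period = _periodic_spline(p)
    t_dense = np.linspace(0.0, period, _DENSE + 1)
    dense = spline(t_dense)
    t0 = _posterior_ray_param(spline, period, centroid, t_dense, dense[:, :2])
    t_k = _equal_arc_params(t_dense, dense, t0, period, n_pts)
    return spline(t_k)


def resample_contour(
    points: np.ndarray, centroid: np.ndarray | None = None, n_pts: int = 50
) -> np.ndarray:
    """Resample a closed planar contour to ``n_pts`` points at equal arc length
    on the periodic cubic spline through the input points.

    Point 0 is the spline's crossing of the ray from ``centroid`` (default:
    polygon area centroid) in the posterior (−y) direction; subsequent points
    run counter-clockwise viewed from +z.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("resample_contour expects an (n, 2) planar contour")
    return _resample_any(p, n_pts, centroid)


# ---------------------------------------------------------------------------
# slice interpolation / trimming / mirroring


def _common_parameterization(
    stack: ContourStack, n_pts: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Resample every slice to the common posterior-ray parameterization.

    Returns (z values, (n_slices, n_pts, 2) array).
    """
    zs = np.array([z for z, _ in stack.slices])
    contours = np.stack([resample_contour(pts, n_pts=n_pts) for _, pts in stack.slices])
    return zs, contours


def _blend_at(z: float, zs: np.ndarray, contours: np.ndarray) -> np.ndarray:
    """Contour at height z by pointwise linear blend of the bracketing slices."""
    i = int(np.clip(np.searchsorted(zs, z, side="right") - 1, 0, len(zs) - 2))
    z0, z1 = zs[i], zs[i + 1]
    w = 0.0 if z1 == z0 else (z - z0) / (z1 - z0)
    return (1.0 - w) * contours[i] + w * contours[i + 1]


def interpolate_slices(stack: ContourStack, n_out: int = 100) -> ContourStack:
    """Densify a stack to ``n_out`` slices spanning [min z, max z] uniformly.

    Each output contour is the pointwise linear blend of the two bracketing
    input contours after both are put in the common 50-point posterior-ray
    parameterization.
    """
    if len(stack.slices) < 2:
        raise ValueError("interpolate_slices needs at least 2 slices")
    zs, contours = _common_parameterization(stack)
    z_out = np.linspace(zs[0], zs[-1], n_out)
    new = [(float(z), _blend_at(z, zs, contours)) for z in z_out]
    return ContourStack(meta=stack.meta, slices=new)


def trim_canal(stack: ContourStack, meta: SpecimenMeta | None = None) -> ContourStack:
    """Trim to the analysis window: z in [gt_z − 0.321·L_femur, gt_z − 0.10·L_femur].

    The retained segment equals 22.1% of femur length, starting 10% of femur
    length distal to the GT landmark.  Boundary contours are synthesized by
    interpolation at the exact cut heights.
    """
    meta = meta or stack.meta
    if not (meta.femur_length > 0) or not np.isfinite(meta.gt_z):
        raise ValueError(f"specimen {meta.id}: femur_length and gt_z required")
    hi = meta.gt_z - TRIM_PROXIMAL_FRAC * meta.femur_length
    lo = hi - TRIM_LENGTH_FRAC * meta.femur_length
    zs = np.array([z for z, _ in stack.slices])
    eps = 1e-9 * max(1.0, meta.femur_length)
    if zs[0] > lo + eps or zs[-1] < hi - eps:
        raise ValueError(
            f"specimen {meta.id}: stack spans [{zs[0]:.3f}, {zs[-1]:.3f}] mm but the "
            f"trim window needs [{lo:.3f}, {hi:.3f}] mm"
        )
    zs_c, contours = _common_parameterization(stack)
    inner = [
        (float(z), pts)
        for (z, _), pts in zip(stack.slices, contours)
        if lo + eps < z < hi - eps
    ]
    new = [(float(lo), _blend_at(lo, zs_c, contours))] + inner + [
        (float(hi), _blend_at(hi, zs_c, contours))
    ]
    return ContourStack(meta=stack.meta, slices=new)


def mirror_to_right(stack: ContourStack) -> ContourStack:
    """Mirror left femora about the sagittal plane (x → −x) so every specimen
    is right-sided; point order is reversed to restore the counter-clockwise
    convention.  Right stacks pass through unchanged."""
    side = stack.meta.side
    if side == "right":
        return stack.copy()
    if side != "left":
        raise ValueError(f"specimen {stack.meta.id}: side is {side!r}; need left/right")
    new_slices = []
    for z, pts in stack.slices:
        q = np.asarray(pts, float).copy()
        q[:, 0] = -q[:, 0]
        new_slices.append((z, q[::-1]))
    return ContourStack(meta=replace(stack.meta, side="right"), slices=new_slices)


# ---------------------------------------------------------------------------
# MVEE and alignment


def fit_mvee(points: np.ndarray, tol: float = 1e-6, max_iter: int = 10000) -> Ellipsoid:
    """Minimum-volume enclosing ellipsoid by Khachiyan-type barycentric ascent
    with away steps (Todd–Yıldırım), which converges linearly.

    Point weights u are updated toward the worst-contained point (add step) or
    away from an over-weighted interior point (away step) until either the
    duality gap max_i q_i^T X(u)^{-1} q_i − (d+1) falls below tol·(d+1) or the
    weight update ||u_new − u|| falls below tol (the stopping rule of the
    standard reference implementation), or the dual objective log det X(u)
    stops improving at float64 resolution.  The returned ellipsoid is inflated
    by the final worst quadratic form, so every input point is inside within
    floating-point error regardless of where the iteration stopped.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("fit_mvee expects (n, 3) points")
    n, d = P.shape
    if n < 4 or np.linalg.matrix_rank(P - P.mean(axis=0), tol=1e-9 * max(1.0, np.abs(P).max())) < d:
        raise ValueError("MVEE needs >= 4 non-coplanar points")
    Q = np.column_stack([P, np.ones(n)])  # (n, d+1)
    # Kumar–Yildirim initialization: weight the extreme points along each
    # coordinate direction of an orthogonalized basis
    u = np.zeros(n)
    basis = np.eye(d)
    seeds: list[int] = []
    for k in range(d):
        proj = P @ basis[:, k]
        seeds.extend([int(np.argmin(proj)), int(np.argmax(proj))])
    seeds = sorted(set(seeds))
    u[seeds] = 1.0 / len(seeds)
    err = np.inf
    best_logdet = -np.inf
    stagnant = 0
    for _ in range(max_iter):
        X = Q.T @ (Q * u[:, None])  # (d+1, d+1)
        sign, logdet = np.linalg.slogdet(X)
        if sign > 0 and logdet > best_logdet + 1e-14 * max(1.0, abs(best_logdet)):
            best_logdet = logdet
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= 100:  # converged to float64 resolution
                break
        M = np.einsum("ij,ij->i", Q @ np.linalg.inv(X), Q)
        j_add = int(np.argmax(M))
        kappa_add = M[j_add]
        err = kappa_add / (d + 1) - 1.0
        if err <= tol:
            break
        support = u > 0
        j_away = int(np.where(support)[0][np.argmin(M[support])])
        kappa_away = M[j_away]
        u_prev = u.copy()
        if kappa_add - (d + 1) >= (d + 1) - kappa_away:
            step = (kappa_add - d - 1.0) / ((d + 1.0) * (kappa_add - 1.0))
            u *= 1.0 - step
            u[j_add] += step
        else:
            step = (d + 1.0 - kappa_away) / ((d + 1.0) * (kappa_away - 1.0))
            cap = u[j_away] / (1.0 - u[j_away])
            drop = step >= cap
            step = min(step, cap)
            u *= 1.0 + step
            u[j_away] = 0.0 if drop else u[j_away] - step
            np.clip(u, 0.0, None, out=u)
            u /= u.sum()
        if np.linalg.norm(u - u_prev) < tol:
            break
    else:
        raise RuntimeError(
            f"MVEE did not converge in {max_iter} iterations (residual {err:.3e})"
        )
    c = P.T @ u
    A = np.linalg.inv(P.T @ (P * u[:, None]) - np.outer(c, c)) / d
    w, V = np.linalg.eigh(A)  # ascending eigenvalues -> descending radii
    radii = 1.0 / np.sqrt(w)
    order = np.argsort(radii)[::-1]
    ell = Ellipsoid(center=c, axes=V[:, order], radii=radii[order])
    qmax = float(ell.quadratic_form(P).max())
    if qmax > 1.0:  # inflate so containment holds exactly
        ell = Ellipsoid(center=c, axes=ell.axes, radii=ell.radii * np.sqrt(qmax))
    return ell


def alignment_rotation(ell: Ellipsoid, iso_tol: float = 1e-3) -> np.ndarray:
    """Rotation matrix R (rows = new axes) taking world coordinates into the
    ellipsoid principal frame.

    Axis assignment: longest ellipsoid axis → z; the remaining two go to x and
    y so as to maximize absolute dot products with the incoming x and y; each
    new axis is sign-flipped if its dot product with the old same-name axis is
    negative; det = +1 is enforced by flipping y if necessary.  A near-
    isotropic ellipsoid (radii within 0.1%) keeps the incoming frame.
    """
    r = ell.radii
    if (r.max() - r.min()) / r.max() < iso_tol:
        warnings.warn(
            "near-isotropic MVEE: keeping incoming axis order", RuntimeWarning
        )
        return np.eye(3)
    new_z = ell.axes[:, 0]  # longest
    rest = [ell.axes[:, 1], ell.axes[:, 2]]
    ex, ey = np.eye(3)[0], np.eye(3)[1]
    # assign the transverse pair to (x, y) maximizing |dot| with the old axes
    if abs(rest[0] @ ex) + abs(rest[1] @ ey) >= abs(rest[1] @ ex) + abs(rest[0] @ ey):
        new_x, new_y = rest[0], rest[1]
    else:
        new_x, new_y = rest[1], rest[0]
    if new_x @ ex < 0:
        new_x = -new_x
    if new_y @ ey < 0:
        new_y = -new_y
    if new_z @ np.array([0.0, 0.0, 1.0]) < 0:
        new_z = -new_z
    R = np.vstack([new_x, new_y, new_z])
    if np.linalg.det(R) < 0:
        R[1] = -R[1]
    return R


def align_to_ellipsoid(stack: ContourStack, ell: Ellipsoid) -> RotatedStack:
    """Express a centered stack in the MVEE principal frame.

    The original CT planes tilt under the rotation, so the result is a stack of
    3-D rings (consumed by :func:`reslice_sections`), ordered by mean z.
    """
    R = alignment_rotation(ell)
    rings = []
    for z, pts in stack.slices:
        ring = np.column_stack([pts, np.full(len(pts), z)]) @ R.T
        rings.append(ring)
    rings.sort(key=lambda r: float(r[:, 2].mean()))
    return RotatedStack(meta=stack.meta, rings=rings)


def reslice_sections(stack: RotatedStack, n_sections: int = 30) -> ContourStack:
    """Cut ``n_sections`` planar sections at uniform z in the aligned frame.

    Each ring is first put into the common 50-point posterior-ray
    parameterization (carrying z per point); the section at a cut height is
    then obtained by linear interpolation in z along each corresponded point
    trajectory.  Sections are labeled 0 (distal) to n_sections−1 (proximal).
    """
    if n_sections < 2:
        raise ValueError("n_sections must be >= 2")
    rings = np.stack([_resample_any(r, 50) for r in stack.rings])  # (K, 50, 3)
    zcols = rings[:, :, 2]  # (K, 50)
    if np.any(np.diff(zcols, axis=0) <= 0):
        raise ValueError(
            "ring z-order not monotone along the stack; alignment tilted the "
            "slices too strongly to reslice"
        )
    z_lo = float(zcols[0].max())
    z_hi = float(zcols[-1].min())
    z_out = np.linspace(z_lo, z_hi, n_sections)
    slices = []
    for z in z_out:
        pts = np.empty((rings.shape[1], 2))
        for j in range(rings.shape[1]):
            pts[j, 0] = np.interp(z, zcols[:, j], rings[:, j, 0])
            pts[j, 1] = np.interp(z, zcols[:, j], rings[:, j, 1])
        slices.append((float(z), pts))
    return ContourStack(meta=stack.meta, slices=slices)


# ---------------------------------------------------------------------------
# full pipeline


def build_correspondence(
    stack: ContourStack,
    meta: SpecimenMeta | None = None,
    n_interp_slices: int = 100,
    n_sections: int = 30,
    n_points: int = 50,
    mvee_tol: float = 1e-6,
) -> AlignedShape:
    """Run the full preprocessing chain on a raw validated stack and return the
    30 × 50 point-correspondent shape with its segment length."""
    meta = meta or stack.meta
    stage = "validate"
    try:
        validate_stack(stack)
        stage = "interpolate_slices"
        dense = interpolate_slices(stack, n_out=n_interp_slices)
        stage = "trim_canal"
        trimmed = trim_canal(dense, meta)
        stage = "mirror_to_right"
        mirrored = mirror_to_right(trimmed)
        stage = "center"
        pts = mirrored.all_points()
        centroid = pts.mean(axis=0)
        centered = ContourStack(
            meta=mirrored.meta,
            slices=[
                (float(z - centroid[2]), p - centroid[:2])
                for z, p in mirrored.slices
            ],
        )
        stage = "fit_mvee"
        ell = fit_mvee(centered.all_points(), tol=mvee_tol)
        stage = "align_to_ellipsoid"
        rotated = align_to_ellipsoid(centered, ell)
        stage = "reslice_sections"
        resliced = reslice_sections(rotated, n_sections=n_sections)
        stage = "resample_contour"
        sections = np.empty((n_sections, n_points, 3))
        for k, (z, p) in enumerate(resliced.slices):
            sections[k, :, :2] = resample_contour(p, n_pts=n_points)
            sections[k, :, 2] = z
    except Exception as e:
        raise PipelineError(
            f"specimen {meta.id}: stage {stage!r} failed: {e}"
        ) from e
    return AlignedShape(
        meta=mirrored.meta,
        sections=sections,
        segment_length=TRIM_LENGTH_FRAC * meta.femur_length,
    )
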