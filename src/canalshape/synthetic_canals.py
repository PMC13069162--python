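"""Parametric synthetic canal generator with exact ground truth.

Stands in for patient data (which are not publicly available): each specimen
is a stack of elliptical cross-sections along a gently curved centerline with

* a proximal flare in equivalent radius, r_eq(t) = r0·(1 + (F−1)·h(t)) with
  h the smoothstep profile 3t²−2t³ and t ∈ [0, 1] along the retained segment,
* an area-preserving aspect ratio (semi-axes a = r√ρ, b = r/√ρ), so r_eq and
  the roundness index are independently controllable and ground truth exact,
* a linear twist of the major axis, φ(t) = φ0 + Δφ·t,
* section centroids on a circular arc of radius R_c in the x–z plane with
  sections kept perpendicular to z (matching the planar-section pipeline and
  keeping the sphere-fit ground truth exact for small L/R_c),
* optional isotropic in-plane Gaussian point noise.

Slices are embedded in a longer dummy femur (GT placed so the generated
segment is exactly the trimming window) so the full pipeline — interpolation,
trimming, mirroring, alignment — is exercised.  Generation is deterministic
given the parameters; the seed drives only point noise, so noiseless stacks
are identical across seeds.

Default parameter scales follow the source-data regime: femur length ≈ 420 mm
(retained segment ≈ 93 mm), distal equivalent radius ≈ 7 mm, flare ≈ 1.6,
roundness ≈ 1.3, twist ≈ 15°, centerline radius ≈ 1000 mm, slice spacing
within 5–10 mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .canal_features import FeatureSummary
from .contour_io import AlignedShape, ContourStack, SpecimenMeta, validate_stack
from .preprocess import TRIM_LENGTH_FRAC, TRIM_PROXIMAL_FRAC

__all__ = [
    "SyntheticParams",
    "CohortSpec",
    "smoothstep",
    "generate_specimen",
    "generate_aligned_shape",
    "generate_cohort",
    "generate_aligned_cohort",
    "truths_to_frame",
]

_MARGIN_MM = 12.0  # extra stack extent beyond the trim window, each side

FLARE_PROFILES = {
    "smoothstep": lambda t: 3.0 * t**2 - 2.0 * t**3,
    "linear": lambda t: t,
}


def smoothstep(t: np.ndarray) -> np.ndarray:
    """Default flare profile h(t) = 3t² − 2t³ (monotone, h(0)=0, h(1)=1)."""
    return FLARE_PROFILES["smoothstep"](np.asarray(t, dtype=float))


@dataclass(frozen=True)
class SyntheticParams:
    """Ground-truth parameters of one synthetic canal (units: mm, degrees)."""

    r0: float = 7.0  # distal equivalent radius
    F: float = 1.6  # flare index (max/min r_eq over the segment)
    flare_profile: str = "smoothstep"
    rho: float = 1.3  # roundness (ellipse aspect ratio), constant
    delta_phi: float = 15.0  # total twist of the major axis, degrees
    R_c: float = 1000.0  # centerline arc radius; inf = straight
    femur_length: float = 420.0
    L: float | None = None  # segment length; default 0.221 * femur_length
    phi0: float = 20.0  # distal major-axis angle, degrees
    n_slices: int = 22
    pts_per_slice: int = 50
    noise_sd: float = 0.0  # in-plane point noise, mm
    side: str = "right"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.F >= 1.0 and self.rho >= 1.0):
            raise ValueError("F and rho must be >= 1")
        if self.n_slices < 2 or self.pts_per_slice < 8:
            raise ValueError("need >= 2 slices and >= 8 points per slice")
        if self.flare_profile not in FLARE_PROFILES:
            raise ValueError(f"unknown flare profile {self.flare_profile!r}")
        L = self.segment_length
        if not (0 < L < self.femur_length):
            raise ValueError("segment length must be positive and < femur length")
        if self.R_c <= 0:
            raise ValueError("R_c must be positive (use inf for straight)")

    @property
    def segment_length(self) -> float:
        return self.L if self.L is not None else TRIM_LENGTH_FRAC * self.femur_length


def _profile_fn(params: SyntheticParams):
    return FLARE_PROFILES[params.flare_profile]


def _section_geometry(params: SyntheticParams, t: np.ndarray):
    """Per-section ellipse parameters at normalized heights t (clipped to
    [0, 1] outside the segment so trimmed margins extend the end sections)."""
    h = _profile_fn(params)(np.clip(t, 0.0, 1.0))
    r = params.r0 * (1.0 + (params.F - 1.0) * h)
    a = r * math.sqrt(params.rho)
    b = r / math.sqrt(params.rho)
    phi = np.radians(params.phi0 + params.delta_phi * np.clip(t, 0.0, 1.0))
    return r, a, b, phi


def _arc_offset(params: SyntheticParams, s: np.ndarray) -> np.ndarray:
    """Centroid x-offset: points on a circle of radius R_c in the x–z plane,
    s the signed height from the segment midpoint."""
    if np.isinf(params.R_c):
        return np.zeros_like(s)
    return params.R_c - np.sqrt(params.R_c**2 - s**2)


def _ellipse_points(
    a: float, b: float, phi: float, center_x: float, n: int
) -> np.ndarray:
    theta = 2.0 * np.pi * np.arange(n) / n - np.pi / 2.0  # start posterior-ish, CCW
    u = a * np.cos(theta)
    v = b * np.sin(theta)
    x = center_x + u * np.cos(phi) - v * np.sin(phi)
    y = u * np.sin(phi) + v * np.cos(phi)
    return np.column_stack([x, y])


def ground_truth(params: SyntheticParams, n_sections: int = 30) -> FeatureSummary:
    """Exact feature summary implied by the generator parameters, evaluated at
    the section heights the pipeline will use (t_k = k/(n_sections−1))."""
    t = np.linspace(0.0, 1.0, n_sections)
    h = _profile_fn(params)(t)
    L = params.segment_length
    curv = 0.0 if np.isinf(params.R_c) else 1.0 / params.R_c
    return FeatureSummary(
        mean_r_eq_over_L=float(params.r0 / L * np.mean(1.0 + (params.F - 1.0) * h)),
        mean_mri=params.rho,
        delta_phi=params.delta_phi,
        flare_index=params.F,
        curvature=curv,
        normalized_curvature=0.0 if np.isinf(params.R_c) else L / params.R_c,
    )


def generate_specimen(
    params: SyntheticParams,
    specimen_id: str = "synthetic",
    sex: str = "unknown",
    age: float = float("nan"),
) -> tuple[ContourStack, FeatureSummary]:
    """Raw contour stack for one synthetic canal plus its exact ground truth.

    The GT landmark is placed at z = 0, so the trim window is
    [−0.321·L_femur, −0.10·L_femur]; the generated flare/twist segment spans
    exactly that window, with constant-profile margins beyond both cuts.
    """
    L = params.segment_length
    hi = -TRIM_PROXIMAL_FRAC * params.femur_length
    lo = hi - L
    z = np.linspace(lo - _MARGIN_MM, hi + _MARGIN_MM, params.n_slices)
    t = (z - lo) / L
    _, a, b, phi = _section_geometry(params, t)
    x_c = _arc_offset(params, z - (lo + hi) / 2.0)
    rng = np.random.default_rng(params.seed)
    slices = []
    for k in range(params.n_slices):
        pts = _ellipse_points(a[k], b[k], phi[k], x_c[k], params.pts_per_slice)
        if params.noise_sd > 0:
            pts = pts + rng.normal(0.0, params.noise_sd, size=pts.shape)
        slices.append((float(z[k]), pts))
    stack = ContourStack(
        meta=SpecimenMeta(
            id=specimen_id,
            sex=sex,
            age=age,
            side="right",
            femur_length=params.femur_length,
            gt_z=0.0,
        ),
        slices=slices,
    )
    if params.side == "left":
        mirrored = []
        for zk, pts in stack.slices:
            q = pts.copy()
            q[:, 0] = -q[:, 0]
            mirrored.append((zk, q[::-1]))
        stack = ContourStack(
            meta=replace(stack.meta, side="left"), slices=mirrored
        )
    validate_stack(stack)
    return stack, ground_truth(params)


def generate_aligned_shape(
    params: SyntheticParams,
    specimen_id: str = "synthetic",
    n_sections: int = 30,
    n_points: int = 50,
) -> AlignedShape:
    """Idealized corresponded shape straight from the generator equations
    (30 planar sections over the segment, no preprocessing).

    Used for cohort-scale shape-model experiments where running the full
    geometric pipeline per specimen would only add the (separately validated)
    resampling noise.
    """
    L = params.segment_length
    t = np.linspace(0.0, 1.0, n_sections)
    _, a, b, phi = _section_geometry(params, t)
    zs = t * L
    x_c = _arc_offset(params, zs - L / 2.0)
    rng = np.random.default_rng(params.seed)
    sections = np.empty((n_sections, n_points, 3))
    for k in range(n_sections):
        pts = _ellipse_points(a[k], b[k], phi[k], x_c[k], n_points)
        if params.noise_sd > 0:
            pts = pts + rng.normal(0.0, params.noise_sd, size=pts.shape)
        sections[k, :, :2] = pts
        sections[k, :, 2] = zs[k]
    return AlignedShape(
        meta=SpecimenMeta(
            id=specimen_id,
            side="right",
            femur_length=params.femur_length,
            gt_z=0.0,
        ),
        sections=sections,
        segment_length=L,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Distributional recipe for a synthetic cohort.

    Each (mean, sd) pair draws the corresponding generator parameter from a
    normal distribution (clipped to its valid range); sd = 0 fixes the value.
    ``sex_offsets`` optionally shifts parameter means for male specimens
    (sex assigned F/M with equal probability).
    """

    n: int = 100
    seed: int = 0
    r0: tuple[float, float] = (7.0, 0.8)
    F: tuple[float, float] = (1.6, 0.15)
    rho: tuple[float, float] = (1.3, 0.1)
    delta_phi: tuple[float, float] = (15.0, 5.0)
    R_c: tuple[float, float] = (1000.0, 0.0)
    femur_length: tuple[float, float] = (420.0, 25.0)
    noise_sd: float = 0.0
    sex_offsets: dict | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort needs n >= 2")
        for name in ("r0", "F", "rho", "delta_phi", "R_c", "femur_length"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name}: sd must be >= 0")


def _draw_params(spec: CohortSpec, rng: np.random.Generator):
    def draw(pair, lo=None, hi=None, shift=0.0):
        mean, sd = pair
        v = rng.normal(mean + shift, sd) if sd > 0 else mean + shift
        if lo is not None:
            v = max(v, lo)
        if hi is not None:
            v = min(v, hi)
        return float(v)

    sex = "M" if rng.random() < 0.5 else "F"
    off = (spec.sex_offsets or {}) if sex == "M" else {}
    femur = draw(spec.femur_length, lo=250.0, shift=off.get("femur_length", 0.0))
    span = TRIM_LENGTH_FRAC * femur + 2 * _MARGIN_MM
    spacing = rng.uniform(5.0, 10.0)  # source-protocol slice spacing
    n_slices = max(int(math.ceil(span / spacing)) + 1, 12)
    params = SyntheticParams(
        r0=draw(spec.r0, lo=2.0, shift=off.get("r0", 0.0)),
        F=draw(spec.F, lo=1.0, shift=off.get("F", 0.0)),
        rho=draw(spec.rho, lo=1.0, shift=off.get("rho", 0.0)),
        delta_phi=draw(spec.delta_phi, shift=off.get("delta_phi", 0.0)),
        R_c=draw(spec.R_c, lo=300.0, shift=off.get("R_c", 0.0)),
        femur_length=femur,
        n_slices=n_slices,
        noise_sd=spec.noise_sd,
        side="left" if rng.random() < 0.5 else "right",
        seed=int(rng.integers(2**31)),
    )
    return params, sex


def generate_cohort(
    spec: CohortSpec,
) -> list[tuple[ContourStack, FeatureSummary]]:
    """Raw contour stacks with recorded ground truths, reproducible from the
    cohort seed."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for i in range(spec.n):
        params, sex = _draw_params(spec, rng)
        age = float(rng.uniform(20.0, 92.0))
        out.append(
            generate_specimen(params, specimen_id=f"syn{i:04d}", sex=sex, age=age)
        )
    return out


def generate_aligned_cohort(
    spec: CohortSpec, n_sections: int = 30, n_points: int = 50
) -> tuple[list[AlignedShape], pd.DataFrame]:
    """Idealized corresponded cohort plus a ground-truth table (fast path for
    shape-model experiments; same parameter draws as generate_cohort)."""
    rng = np.random.default_rng(spec.seed)
    shapes, rows = [], []
    for i in range(spec.n):
        params, sex = _draw_params(spec, rng)
        float(rng.uniform(20.0, 92.0))  # keep the draw sequence identical
        sid = f"syn{i:04d}"
        shapes.append(
            generate_aligned_shape(params, specimen_id=sid, n_sections=n_sections,
                                   n_points=n_points)
        )
        truth = ground_truth(params, n_sections=n_sections)
        rows.append(
            {
                "specimen_id": sid,
                "sex": sex,
                "r0": params.r0,
                "mean_r_eq_over_L": truth.mean_r_eq_over_L,
                "mean_mri": truth.mean_mri,
                "delta_phi": truth.delta_phi,
                "flare_index": truth.flare_index,
                "normalized_curvature": truth.normalized_curvature,
            }
        )
    return shapes, pd.DataFrame(rows).set_index("specimen_id")


def generate_radius_assoc_cohort(
    n: int = 300,
    seed: int = 0,
    target_r2: float = 0.9,
    r0_mean: float = 7.0,
    r0_sd: float = 0.8,
    noise_sd: float = 0.3,
) -> tuple[list[AlignedShape], np.ndarray]:
    """Cohort with a single radius latent factor whose association with the
    measured radius feature has a known population R².

    Only r0 varies across specimens, so the leading shape mode is the radius
    mode and its score is (up to PCA estimation error at realistic point
    noise) proportional to r0.  The per-specimen radius feature is the exact
    generator value plus Gaussian measurement error calibrated so that
    R² = Var(signal)/(Var(signal) + Var(error)) = ``target_r2``.

    Returns (shapes, feature values).
    """
    base = SyntheticParams(r0=r0_mean)
    # feature is linear in r0: t(r0) = r0/L * mean(1 + (F-1) h)
    slope = ground_truth(replace(base, r0=1.0)).mean_r_eq_over_L
    eta_sd = slope * r0_sd * math.sqrt(1.0 / target_r2 - 1.0)
    rng = np.random.default_rng(seed)
    r0s = rng.normal(r0_mean, r0_sd, size=n)
    shapes, feature = [], np.empty(n)
    for i, r0 in enumerate(r0s):
        params = replace(
            base, r0=float(r0), noise_sd=noise_sd, seed=int(rng.integers(2**31))
        )
        shapes.append(generate_aligned_shape(params, specimen_id=f"rad{i:04d}"))
        feature[i] = ground_truth(params).mean_r_eq_over_L + rng.normal(0.0, eta_sd)
    return shapes, feature


def truths_to_frame(
    cohort: list[tuple[ContourStack, FeatureSummary]]
) -> pd.DataFrame:
    """Ground-truth table for a raw cohort, indexed by specimen id."""
    rows = []
    for stack, truth in cohort:
        rows.append(
            {
                "specimen_id": stack.meta.id,
                "sex": stack.meta.sex,
                "side": stack.meta.side,
                "femur_length": stack.meta.femur_length,
                "mean_r_eq_over_L": truth.mean_r_eq_over_L,
                "mean_mri": truth.mean_mri,
                "delta_phi": truth.delta_phi,
                "flare_index": truth.flare_index,
                "normalized_curvature": truth.normalized_curvature,
            }
        )
    return pd.DataFrame(rows).set_index("specimen_id")
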