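"""Specimen interchange formats and correspondence export.

The canal pipeline consumes *contour stacks*: per specimen, an ordered list of
axial slices, each a closed planar polygon of endosteal perimeter points, plus
metadata (sex, age, side, femur length, greater-trochanter landmark height).
Two equivalent on-disk dialects are supported:

* JSON — ``{"specimens": [{"meta": {...}, "slices": [{"z": .., "points":
  [[x, y], ...]}, ...]}, ...]}``
* long-form CSV — one row per perimeter point with columns ``specimen_id,
  slice_index, z, point_index, x, y`` plus the metadata columns repeated on
  every row (``sex, age, side, femur_length, gt_z, tlt_z``).

Units are millimetres throughout. z increases distal→proximal; +x is
pseudo-lateral and +y pseudo-anterior, so the posterior direction is −y.

Corresponded shapes (30 sections × 50 points) are exported as long-form CSV or
ASCII PLY point clouds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpecimenMeta",
    "ContourStack",
    "AlignedShape",
    "SchemaError",
    "ValidationError",
    "validate_stack",
    "read_specimens",
    "write_specimens",
    "write_correspondence",
    "read_correspondence",
]

SEXES = ("F", "M", "unknown")
SIDES = ("left", "right")


class SchemaError(ValueError):
    """The file does not conform to the documented interchange schema."""


class ValidationError(ValueError):
    """A contour stack violates a structural invariant."""


@dataclass(frozen=True)
class SpecimenMeta:
    """Per-specimen metadata.

    gt_z is the z-height (mm) of the most superior point of the greater
    trochanter in the stack's frame; it anchors proximal trimming.  tlt_z (top
    of lesser trochanter) is optional and informational.
    """

    id: str
    sex: str = "unknown"
    age: float = float("nan")
    side: str = "right"
    femur_length: float = float("nan")
    gt_z: float = float("nan")
    tlt_z: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"specimen {self.id}: sex must be one of {SEXES}")
        if self.side not in SIDES + ("unknown",):
            raise ValidationError(f"specimen {self.id}: side must be left/right")


@dataclass
class ContourStack:
    """Ordered axial slices of closed 2-D endosteal contours with z-heights.

    ``slices`` holds ``(z, points)`` pairs with z strictly increasing
    distal→proximal and ``points`` an (n, 2) float array; the first point is
    not repeated at the end.
    """

    meta: SpecimenMeta
    slices: list[tuple[float, np.ndarray]] = field(default_factory=list)

    def all_points(self) -> np.ndarray:
        """All contour points as an (N, 3) array."""
        rows = [
            np.column_stack([pts, np.full(len(pts), z)]) for z, pts in self.slices
        ]
        return np.concatenate(rows, axis=0)

    def copy(self) -> "ContourStack":
        return ContourStack(
            meta=self.meta, slices=[(z, pts.copy()) for z, pts in self.slices]
        )


@dataclass
class AlignedShape:
    """Point-correspondent shape: 30 sections × 50 points × 3 coordinates (mm)
    in the standardized aligned frame, plus the retained segment length L."""

    meta: SpecimenMeta
    sections: np.ndarray  # (n_sections, n_points, 3)
    segment_length: float

    def __post_init__(self) -> None:
        s = np.asarray(self.sections, dtype=float)
        if s.ndim != 3 or s.shape[2] != 3:
            raise ValidationError("sections must be (n_sections, n_points, 3)")
        z = s[:, :, 2]
        if not np.allclose(z, z[:, :1], atol=1e-6):
            raise ValidationError("each section must be planar (constant z)")
        zs = z[:, 0]
        if np.any(np.diff(zs) <= 0):
            raise ValidationError("section z must increase strictly with index")
        self.sections = s


def validate_stack(stack: ContourStack, min_points: int = 8) -> None:
    """Check ContourStack invariants, raising ValidationError on the first hit.

    Self-intersection is deliberately not checked; only point count,
    closedness (first point not repeated) and z-monotonicity are enforced.
    """
    sid = stack.meta.id
    if len(stack.slices) == 0:
        raise ValidationError(f"specimen {sid}: empty stack")
    zs = np.array([z for z, _ in stack.slices], dtype=float)
    if np.any(np.diff(zs) <= 0):
        k = int(np.argmax(np.diff(zs) <= 0)) + 1
        raise ValidationError(
            f"specimen {sid}: slice z not strictly increasing at slice {k}"
        )
    if not (stack.meta.femur_length > 0) and not np.isnan(stack.meta.femur_length):
        raise ValidationError(f"specimen {sid}: femur_length must be > 0")
    if np.isfinite(stack.meta.gt_z) and stack.meta.femur_length > 0:
        lo = zs.min() - stack.meta.femur_length
        hi = zs.max() + stack.meta.femur_length
        if not (lo <= stack.meta.gt_z <= hi):
            raise ValidationError(
                f"specimen {sid}: gt_z={stack.meta.gt_z} outside plausible range "
                f"[{lo}, {hi}]"
            )
    for k, (z, pts) in enumerate(stack.slices):
        pts = np.asarray(pts, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError(f"specimen {sid} slice {k}: points must be (n, 2)")
        if pts.shape[0] < min_points:
            raise ValidationError(
                f"specimen {sid} slice {k}: {pts.shape[0]} points < {min_points}"
            )
        if np.allclose(pts[0], pts[-1]):
            raise ValidationError(
                f"specimen {sid} slice {k}: first point repeated at end "
                "(contours must be implicitly closed)"
            )


# ---------------------------------------------------------------------------
# specimen files


def _meta_to_dict(meta: SpecimenMeta) -> dict:
    d = {
        "id": meta.id,
        "sex": meta.sex,
        "age": meta.age,
        "side": meta.side,
        "femur_length": meta.femur_length,
        "gt_z": meta.gt_z,
    }
    if meta.tlt_z is not None:
        d["tlt_z"] = meta.tlt_z
    return d


def _meta_from_dict(d: dict) -> SpecimenMeta:
    try:
        return SpecimenMeta(
            id=str(d["id"]),
            sex=str(d.get("sex", "unknown")),
            age=float(d.get("age", float("nan"))),
            side=str(d.get("side", "right")),
            femur_length=float(d.get("femur_length", float("nan"))),
            gt_z=float(d.get("gt_z", float("nan"))),
            tlt_z=None if d.get("tlt_z") is None else float(d["tlt_z"]),
        )
    except KeyError as e:  # pragma: no cover - trivial re-raise
        raise SchemaError(f"meta block missing required key {e}") from e


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("json", "csv", "ply"):
        return suffix
    raise SchemaError(f"cannot infer format from {path.name}; pass format=")


def write_specimens(
    stacks: Sequence[ContourStack], path: str | Path, format: str | None = None
) -> None:
    """Write contour stacks to JSON or long-form CSV (see module docstring)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        doc = {
            "specimens": [
                {
                    "meta": _meta_to_dict(s.meta),
                    "slices": [
                        {"z": float(z), "points": np.asarray(p, float).tolist()}
                        for z, p in s.slices
                    ],
                }
                for s in stacks
            ]
        }
        path.write_text(json.dumps(doc))
    elif fmt == "csv":
        rows = []
        for s in stacks:
            m = _meta_to_dict(s.meta)
            for k, (z, pts) in enumerate(s.slices):
                pts = np.asarray(pts, float)
                for j, (x, y) in enumerate(pts):
                    rows.append(
                        {
                            "specimen_id": m["id"],
                            "slice_index": k,
                            "z": z,
                            "point_index": j,
                            "x": x,
                            "y": y,
                            "sex": m["sex"],
                            "age": m["age"],
                            "side": m["side"],
                            "femur_length": m["femur_length"],
                            "gt_z": m["gt_z"],
                            "tlt_z": m.get("tlt_z", np.nan),
                        }
                    )
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")
    else:
        raise SchemaError(f"unsupported specimen format: {fmt}")


def read_specimens(path: str | Path, format: str | None = None) -> list[ContourStack]:
    """Read and validate contour stacks from a JSON or CSV interchange file.

    Slices are sorted by z ascending before validation; every returned stack
    satisfies the ContourStack invariants or a ValidationError names the
    offending specimen and slice.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    stacks: list[ContourStack] = []
    if fmt == "json":
        try:
            doc = json.loads(path.read_text())
            specimens = doc["specimens"]
        except (json.JSONDecodeError, KeyError, TypeError) as e:
            raise SchemaError(f"{path.name}: not a valid specimen JSON file: {e}")
        for spec in specimens:
            try:
                meta = _meta_from_dict(spec["meta"])
                slices = [
                    (float(sl["z"]), np.asarray(sl["points"], dtype=float))
                    for sl in spec["slices"]
                ]
            except (KeyError, TypeError, ValueError) as e:
                raise SchemaError(f"{path.name}: malformed specimen entry: {e}")
            slices.sort(key=lambda t: t[0])
            stacks.append(ContourStack(meta=meta, slices=slices))
    elif fmt == "csv":
        df = pd.read_csv(path)
        required = {"specimen_id", "slice_index", "z", "point_index", "x", "y"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"{path.name}: missing columns {sorted(missing)}")
        for sid, g in df.groupby("specimen_id", sort=False):
            first = g.iloc[0]
            tlt = first.get("tlt_z", np.nan)
            meta = SpecimenMeta(
                id=str(sid),
                sex=str(first.get("sex", "unknown")),
                age=float(first.get("age", np.nan)),
                side=str(first.get("side", "right")),
                femur_length=float(first.get("femur_length", np.nan)),
                gt_z=float(first.get("gt_z", np.nan)),
                tlt_z=None if pd.isna(tlt) else float(tlt),
            )
            slices = []
            for _, sl in g.sort_values(["slice_index", "point_index"]).groupby(
                "slice_index", sort=True
            ):
                z = float(sl["z"].iloc[0])
                slices.append((z, sl[["x", "y"]].to_numpy(dtype=float)))
            slices.sort(key=lambda t: t[0])
            stacks.append(ContourStack(meta=meta, slices=slices))
    else:
        raise SchemaError(f"unsupported specimen format: {fmt}")
    for s in stacks:
        validate_stack(s)
    return stacks


# ---------------------------------------------------------------------------
# correspondence export

_CORR_COLUMNS = ["specimen_id", "section", "point", "x", "y", "z"]


def write_correspondence(
    shapes: Sequence[AlignedShape], path: str | Path, format: str | None = None
) -> None:
    """Export corresponded point sets: one record per point with specimen id,
    section index and point index.  CSV (round-trippable) or ASCII PLY."""
    path = Path(path)
    fmt = _infer_format(path, format)
    counts = {s.sections.shape[:2] for s in shapes}
    if len(counts) > 1:
        raise ValidationError(f"heterogeneous point counts across shapes: {counts}")
    if fmt == "csv":
        frames = []
        for s in shapes:
            ns, npt, _ = s.sections.shape
            sec, pt = np.meshgrid(np.arange(ns), np.arange(npt), indexing="ij")
            frames.append(
                pd.DataFrame(
                    {
                        "specimen_id": s.meta.id,
                        "section": sec.ravel(),
                        "point": pt.ravel(),
                        "x": s.sections[:, :, 0].ravel(),
                        "y": s.sections[:, :, 1].ravel(),
                        "z": s.sections[:, :, 2].ravel(),
                    }
                )
            )
        df = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=_CORR_COLUMNS)
        )
        df.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "ply":
        pts = (
            np.concatenate([s.sections.reshape(-1, 3) for s in shapes])
            if shapes
            else np.empty((0, 3))
        )
        with open(path, "w") as f:
            f.write(
                "ply\nformat ascii 1.0\n"
                f"element vertex {len(pts)}\n"
                "property float x\nproperty float y\nproperty float z\n"
                "end_header\n"
            )
            for x, y, z in pts:
                f.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
    else:
        raise SchemaError(f"unsupported correspondence format: {fmt}")


def read_correspondence(path: str | Path) -> dict[str, np.ndarray]:
    """Read a correspondence CSV back into ``{specimen_id: (ns, np, 3) array}``."""
    df = pd.read_csv(path, float_precision="round_trip")
    out: dict[str, np.ndarray] = {}
    for sid, g in df.groupby("specimen_id", sort=False):
        g = g.sort_values(["section", "point"])
        ns = int(g["section"].max()) + 1
        npt = int(g["point"].max()) + 1
        out[str(sid)] = g[["x", "y", "z"]].to_numpy(float).reshape(ns, npt, 3)
    return out
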