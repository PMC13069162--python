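"""Planar polygon primitives shared by preprocessing and feature extraction."""

from __future__ import annotations

import numpy as np


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a simple closed polygon (first point not repeated).

    Positive for counter-clockwise orientation viewed from +z.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[0] < 3 or p.shape[1] != 2:
        raise ValueError("polygon needs >= 3 planar points")
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


def polygon_area(points: np.ndarray) -> float:
    """Absolute polygon area (mm^2)."""
    return abs(signed_area(points))


def area_centroid(points: np.ndarray) -> np.ndarray:
    """Area (not vertex-mean) centroid of a simple closed polygon."""
    p = np.asarray(points, dtype=float)
    a = signed_area(p)
    if abs(a) < 1e-300:
        # degenerate polygon: fall back to vertex mean
        return p.mean(axis=0)
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])
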