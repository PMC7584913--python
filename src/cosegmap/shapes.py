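"""Particle shape metrics for digitized crystal outlines.

Two descriptors compare iridophore guanine crystals between color morphs on
manually delineated polygon outlines:

* roundness = 4*A / (pi * a^2), where A is the polygon area and a the major
  axis of the ellipse with the same second central moments as the filled
  polygon (1 for a circle, b/a for an ellipse with semi-axes a >= b);
* solidity = A / area(convex hull), 1 for convex shapes, < 1 for ragged ones.

Both are invariant to rotation, translation and uniform scaling.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon as ShapelyPolygon


class DegeneratePolygonError(ValueError):
    """Polygon with (numerically) zero area or fewer than three vertices."""


def _as_vertices(polygon) -> np.ndarray:
    pts = np.asarray(polygon, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise DegeneratePolygonError("polygon needs >= 3 (x, y) vertices")
    extent = float(max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1]), 1e-300))
    if np.hypot(*(pts[0] - pts[-1])) <= 1e-9 * extent:  # closed ring repeated
        pts = pts[:-1]
    if len(pts) < 3:
        raise DegeneratePolygonError("polygon needs >= 3 distinct vertices")
    return pts


def _validated(polygon) -> tuple[np.ndarray, ShapelyPolygon]:
    pts = _as_vertices(polygon)
    shp = ShapelyPolygon(pts)
    if not shp.is_valid:
        raise DegeneratePolygonError("polygon is self-intersecting or invalid")
    extent = float(max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1])))
    if shp.area <= 0 or shp.area < 1e-12 * extent**2:
        raise DegeneratePolygonError("polygon has (numerically) zero area")
    return pts, shp


def polygon_moments(polygon) -> tuple[float, np.ndarray]:
    """Area and 2x2 normalized second-central-moment matrix of a polygon.

    Uses the exact shoelace-based closed forms for the moments of the filled
    polygon (not of the vertex point set).
    """
    pts, _ = _validated(polygon)
    pts = pts - pts.mean(axis=0)  # pre-center: avoids cancellation far from 0
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    if area < 0:  # normalize orientation
        x, y = x[::-1], y[::-1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        area = 0.5 * cross.sum()
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    ixx = ((x * x + x * xn + xn * xn) * cross).sum() / 12.0
    iyy = ((y * y + y * yn + yn * yn) * cross).sum() / 12.0
    ixy = ((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross).sum() / 24.0
    mu = np.array(
        [
            [ixx - area * cx * cx, ixy - area * cx * cy],
            [ixy - area * cx * cy, iyy - area * cy * cy],
        ]
    )
    return float(area), mu / area


def roundness(polygon) -> float:
    """4*A / (pi * major_axis^2) of the moment-equivalent fitted ellipse."""
    area, cov = polygon_moments(polygon)
    eigvals = np.linalg.eigvalsh(cov)
    lam_max = float(eigvals[-1])
    if lam_max <= 0:
        raise DegeneratePolygonError("degenerate polygon: zero second moment")
    # Ellipse with semi-axes (sa, sb) has lam_max = sa^2 / 4.
    major_axis = 4.0 * np.sqrt(lam_max)
    return float(4.0 * area / (np.pi * major_axis**2))


def solidity(polygon) -> float:
    """Polygon area divided by its convex-hull area."""
    pts, _ = _validated(polygon)
    shp = ShapelyPolygon(pts - pts.mean(axis=0))  # pre-center for stability
    hull_area = shp.convex_hull.area
    if hull_area <= 0:
        raise DegeneratePolygonError("degenerate polygon: zero hull area")
    return float(shp.area / hull_area)


def group_compare(values_a: Sequence[float], values_b: Sequence[float]) -> dict:
    """Descriptive two-group comparison of a shape metric.

    Reports per-group medians, the Hodges-Lehmann shift estimate (median of
    all pairwise differences b - a), and the Mann-Whitney rank-sum statistic
    with its two-sided p-value, reported descriptively.
    """
    from scipy.stats import mannwhitneyu

    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    shift = float(np.median(np.subtract.outer(b, a)))
    if a.size == b.size and np.array_equal(np.sort(a), np.sort(b)):
        u_stat, p_value = float(a.size * b.size / 2.0), 1.0
    else:
        res = mannwhitneyu(a, b, alternative="two-sided")
        u_stat, p_value = float(res.statistic), float(res.pvalue)
    return {
        "n_a": int(a.size),
        "n_b": int(b.size),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "shift": shift,
        "u_statistic": u_stat,
        "p_value": p_value,
    }


# ---------------------------------------------------------------------------
# outline I/O and synthetic fixtures


def read_outlines(path: str | os.PathLike) -> dict[str, np.ndarray]:
    """Read outlines from CSV with columns shape_id, vertex_index, x, y."""
    df = pd.read_csv(path)
    required = {"shape_id", "vertex_index", "x", "y"}
    if not required <= set(df.columns):
        raise ValueError(f"outline CSV must have columns {sorted(required)}")
    out: dict[str, np.ndarray] = {}
    for shape_id, grp in df.groupby("shape_id", sort=True):
        grp = grp.sort_values("vertex_index")
        out[str(shape_id)] = grp[["x", "y"]].to_numpy(dtype=float)
    return out


def metrics_table(outlines: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for shape_id, poly in outlines.items():
        rows.append(
            {
                "shape_id": shape_id,
                "roundness": roundness(poly),
                "solidity": solidity(poly),
            }
        )
    return pd.DataFrame(rows)


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def synthetic_outlines(
    kind: str, n: int, seed: int = 0
) -> dict[str, np.ndarray]:
    """Synthetic crystal-outline fixtures for the two morph classes.

    ``kind='wildtype'`` yields parallelepiped-like outlines (elongated, convex:
    low roundness, solidity near 1); ``kind='lavender'`` yields rounded,
    ragged outlines (higher roundness, solidity clearly below 1).  Stands in
    for digitized electron-microscopy outlines, which are not distributed.
    """
    rng = np.random.default_rng([seed, {"wildtype": 11, "lavender": 12}[kind]])
    out: dict[str, np.ndarray] = {}
    for i in range(n):
        theta = rng.uniform(0, 2 * np.pi)
        shift = rng.uniform(-50, 50, 2)
        if kind == "wildtype":
            length = rng.uniform(3.0, 6.0)
            width = length * rng.uniform(0.2, 0.4)
            shear = rng.uniform(-0.3, 0.3)
            base = np.array(
                [
                    [0.0, 0.0],
                    [length, 0.0],
                    [length + shear * width, width],
                    [shear * width, width],
                ]
            )
            jitter = rng.normal(0, 0.01 * length, base.shape)
            poly = base + jitter
        else:
            k = int(rng.integers(12, 20))
            ang = np.sort(rng.uniform(0, 2 * np.pi, k))
            radius = rng.uniform(1.5, 3.0)
            r = radius * (1.0 + rng.uniform(-0.35, 0.35, k))
            poly = np.c_[r * np.cos(ang), r * np.sin(ang)]
        poly = poly @ _rot(theta).T + shift
        out[f"{kind}_{i + 1:03d}"] = poly
    return out
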