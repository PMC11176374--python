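"""Polygon and Voronoi helpers used by the synthesis and tessellation stages.

All functions operate on (x, y) coordinates; units are whatever the caller
uses consistently (pixels or micrometres).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import LineString, Polygon, box

from .errors import DegenerateGeometryError

__all__ = [
    "polygon_area",
    "polygon_perimeter",
    "clipped_voronoi",
]


def polygon_area(vertices: np.ndarray) -> float:
    """Unsigned shoelace area of a simple polygon given as an (n, 2) array."""
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    cross = x * np.concatenate((y[1:], y[:1])) - y * np.concatenate((x[1:], x[:1]))
    return 0.5 * abs(cross.sum())


def polygon_perimeter(vertices: np.ndarray) -> float:
    """Total edge length of a closed polygon given as an (n, 2) array."""
    v = np.asarray(vertices, dtype=float)
    if len(v) < 2:
        return 0.0
    dx = np.concatenate((v[1:, 0], v[:1, 0])) - v[:, 0]
    dy = np.concatenate((v[1:, 1], v[:1, 1])) - v[:, 1]
    return float(np.sqrt(dx * dx + dy * dy).sum())


def _ghost_points(bounds: tuple[float, float, float, float]) -> np.ndarray:
    # A distant frame of sites guarantees every real site has a finite region.
    xmin, ymin, xmax, ymax = bounds
    cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    r = 10.0 * max(xmax - xmin, ymax - ymin, 1.0)
    ang = np.linspace(0.0, 2.0 * np.pi, 8, endpoint=False)
    return np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)])


def clipped_voronoi(
    points: np.ndarray,
    bounds: tuple[float, float, float, float],
    min_edge_length: float = 0.0,
):
    """Voronoi partition of ``points`` clipped to a rectangular field.

    Parameters
    ----------
    points : (n, 2) array
        Cell centers; may lie slightly outside the bounds (such cells then
        get an empty clipped polygon).
    bounds : (xmin, ymin, xmax, ymax)
        Rectangular field to clip against.
    min_edge_length : float
        Shared Voronoi edges not longer than this (after clipping) do not
        create a neighbor relation; point contacts are always excluded.

    Returns
    -------
    polygons : list of (k, 2) arrays
        One clipped polygon per input point (empty array if the cell lies
        entirely outside the field). Vertices are ordered counter-clockwise
        without a repeated closing vertex.
    neighbors : list of sets
        ``j in neighbors[i]`` iff cells i and j share a clipped finite edge
        longer than ``min_edge_length``. Symmetric by construction.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise DegenerateGeometryError("need at least 3 points for a Voronoi partition")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("points are collinear")

    n = len(pts)
    vor = Voronoi(np.vstack([pts, _ghost_points(bounds)]))
    field = box(*bounds)
    xmin, ymin, xmax, ymax = bounds

    def _inside(v: np.ndarray) -> bool:
        return bool(
            (v[:, 0] >= xmin).all()
            and (v[:, 0] <= xmax).all()
            and (v[:, 1] >= ymin).all()
            and (v[:, 1] <= ymax).all()
        )

    polygons: list[np.ndarray] = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:  # cannot happen with the ghost frame
            polygons.append(np.empty((0, 2)))
            continue
        coords = vor.vertices[region]
        if not _inside(coords):  # only boundary cells need real clipping
            clipped = Polygon(coords).intersection(field)
            if clipped.is_empty or clipped.area <= 0 or clipped.geom_type != "Polygon":
                polygons.append(np.empty((0, 2)))
                continue
            coords = np.asarray(clipped.exterior.coords[:-1])
        # enforce counter-clockwise orientation in (x, y)
        if _signed_area(coords) < 0:
            coords = coords[::-1]
        polygons.append(coords)

    neighbors: list[set[int]] = [set() for _ in range(n)]
    for (p, q), rv in zip(vor.ridge_points, vor.ridge_vertices):
        if p >= n or q >= n:
            continue
        if -1 in rv:
            continue
        ends = vor.vertices[rv]
        if _inside(ends):
            length = float(np.hypot(*(ends[1] - ends[0])))
        else:
            length = LineString(ends).intersection(field).length
        if length > min_edge_length:
            neighbors[p].add(q)
            neighbors[q].add(p)
    return polygons, neighbors


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
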