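"""Polygon rasterization primitives shared by the measurement and simulation code.

Conventions (fixed for the whole package): coordinates are 0-based and
row-major; a pixel's center sits at integer coordinates ``(x, y)`` =
``(col, row)``.  A pixel belongs to a polygon iff its center is strictly
inside the polygon or lies on its boundary, with insideness decided by the
even-odd (crossing-number) rule.
"""

from __future__ import annotations

import numpy as np

__all__ = ["polygon_mask", "points_in_polygon", "translate_polygon", "polygon_centroid"]

_EDGE_EPS = 1e-9

# rasterizing the same polygon for every frame of a drift-free movie is the
# hot path; memoize on (vertex bytes, shape)
_MASK_CACHE: dict[tuple[bytes, tuple[int, int]], np.ndarray] = {}
_MASK_CACHE_MAX = 4096


def _as_vertices(polygon) -> np.ndarray:
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise ValueError("polygon must be an (n>=3, 2) array of (x, y) vertices")
    return verts


def points_in_polygon(points: np.ndarray, polygon) -> np.ndarray:
    """Even-odd point-in-polygon test, boundary-inclusive.

    Parameters
    ----------
    points : (n, 2) array of (x, y) query points.
    polygon : (m, 2) sequence of (x, y) vertices (implicitly closed).

    Returns
    -------
    (n,) boolean array; True where the point is inside or on an edge.
    """
    verts = _as_vertices(polygon)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    on_edge = np.zeros(len(pts), dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        # boundary test: collinear with the edge and within its bounding box
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        scale = max(abs(x2 - x1), abs(y2 - y1), 1.0)
        collinear = np.abs(cross) <= _EDGE_EPS * scale
        in_box = (
            (x >= min(x1, x2) - _EDGE_EPS)
            & (x <= max(x1, x2) + _EDGE_EPS)
            & (y >= min(y1, y2) - _EDGE_EPS)
            & (y <= max(y1, y2) + _EDGE_EPS)
        )
        on_edge |= collinear & in_box
        # half-open crossing rule; degenerate horizontal edges contribute nothing
        crosses = (y1 > y) != (y2 > y)
        if np.any(crosses):
            with np.errstate(divide="ignore", invalid="ignore"):
                x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            inside ^= crosses & (x < x_int)
    return inside | on_edge


def polygon_mask(shape: tuple[int, int], polygon) -> np.ndarray:
    """Boolean raster mask of a polygon on an image of ``shape`` = (rows, cols)."""
    verts = _as_vertices(polygon)
    key = (verts.tobytes(), tuple(shape))
    cached = _MASK_CACHE.get(key)
    if cached is not None:
        return cached
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    # only evaluate the bounding box
    x_lo = max(int(np.floor(verts[:, 0].min())), 0)
    x_hi = min(int(np.ceil(verts[:, 0].max())), w - 1)
    y_lo = max(int(np.floor(verts[:, 1].min())), 0)
    y_hi = min(int(np.ceil(verts[:, 1].max())), h - 1)
    if x_lo > x_hi or y_lo > y_hi:
        return mask
    xs, ys = np.meshgrid(np.arange(x_lo, x_hi + 1), np.arange(y_lo, y_hi + 1))
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    hit = points_in_polygon(pts, verts).reshape(ys.shape)
    mask[y_lo : y_hi + 1, x_lo : x_hi + 1] = hit
    if len(_MASK_CACHE) >= _MASK_CACHE_MAX:
        _MASK_CACHE.clear()
    mask.setflags(write=False)
    _MASK_CACHE[key] = mask
    return mask


def translate_polygon(polygon, shift: tuple[float, float]) -> np.ndarray:
    """Return the polygon translated by ``shift`` = (dx, dy)."""
    verts = _as_vertices(polygon)
    return verts + np.asarray(shift, dtype=float)


def polygon_centroid(polygon) -> np.ndarray:
    """Area centroid (x, y) of a simple polygon (shoelace formula)."""
    verts = _as_vertices(polygon)
    x, y = verts[:, 0], verts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    if abs(area) < 1e-12:
        return verts.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return np.array([cx, cy])
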