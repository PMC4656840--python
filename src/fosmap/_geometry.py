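"""Low-level computational geometry kernels.

The Monte Carlo spatial-randomness tests need clipped Voronoi tessellations of
many thousands of point subsamples drawn inside the same section polygon, so
the clipped-cell areas are computed by a jit-compiled half-plane clipping
kernel rather than through a general polygon-overlay library.  The Voronoi
cell of point *i* is the intersection of the half-planes bounded by the
perpendicular bisectors with every other point; clipping the (CCW) region ring
by those half-planes with Sutherland-Hodgman yields the cell restricted to the
region.  Degenerate bridge edges produced by clipping a non-convex ring lie on
the clip line and cancel in the shoelace sum, so signed areas stay exact.
"""

from __future__ import annotations

import warnings

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.geometry.polygon import orient

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _clip_halfplane(xs, ys, n, ax, ay, b, out_x, out_y):
    """Clip polygon (xs[:n], ys[:n]) to {p : ax*px + ay*py <= b}."""
    m = 0
    for k in range(n):
        x1 = xs[k]
        y1 = ys[k]
        k2 = k + 1
        if k2 == n:
            k2 = 0
        x2 = xs[k2]
        y2 = ys[k2]
        s1 = ax * x1 + ay * y1 - b
        s2 = ax * x2 + ay * y2 - b
        if s1 <= 0.0:
            out_x[m] = x1
            out_y[m] = y1
            m += 1
            if s2 > 0.0:
                t = s1 / (s1 - s2)
                out_x[m] = x1 + t * (x2 - x1)
                out_y[m] = y1 + t * (y2 - y1)
                m += 1
        elif s2 <= 0.0:
            t = s1 / (s1 - s2)
            out_x[m] = x1 + t * (x2 - x1)
            out_y[m] = y1 + t * (y2 - y1)
            m += 1
    return m


@njit(cache=True)
def _cell_areas_kernel(px, py, ring_x, ring_y):
    n = px.size
    m = ring_x.size
    cap = 4 * (m + n) + 64
    ax1 = np.empty(cap)
    ay1 = np.empty(cap)
    ax2 = np.empty(cap)
    ay2 = np.empty(cap)
    d2 = np.empty(n)
    areas = np.zeros(n)
    for i in range(n):
        for j in range(n):
            dx = px[j] - px[i]
            dy = py[j] - py[i]
            d2[j] = dx * dx + dy * dy
        d2[i] = np.inf
        order = np.argsort(d2)
        na = m
        for k in range(m):
            ax1[k] = ring_x[k]
            ay1[k] = ring_y[k]
        # max squared vertex distance from the generating point
        r2 = 0.0
        for k in range(na):
            dx = ax1[k] - px[i]
            dy = ay1[k] - py[i]
            v = dx * dx + dy * dy
            if v > r2:
                r2 = v
        for jj in range(n - 1):
            j = order[jj]
            # a bisector at distance d/2 >= R cannot cut the current cell,
            # and the remaining points are farther still
            if d2[j] >= 4.0 * r2:
                break
            if na == 0:
                break
            dx = px[j] - px[i]
            dy = py[j] - py[i]
            b = 0.5 * (dx * (px[i] + px[j]) + dy * (py[i] + py[j]))
            na = _clip_halfplane(ax1, ay1, na, dx, dy, b, ax2, ay2)
            r2 = 0.0
            for k in range(na):
                ax1[k] = ax2[k]
                ay1[k] = ay2[k]
                ddx = ax1[k] - px[i]
                ddy = ay1[k] - py[i]
                v = ddx * ddx + ddy * ddy
                if v > r2:
                    r2 = v
        s = 0.0
        for k in range(na):
            k2 = k + 1
            if k2 == na:
                k2 = 0
            s += ax1[k] * ay1[k2] - ax1[k2] * ay1[k]
        areas[i] = 0.5 * abs(s)
    return areas


@njit(cache=True)
def _subsample_entropies(px, py, ring_x, ring_y, idx_matrix):
    """Voronoi entropy for each row of subsample indices (N_sim x n_sub)."""
    n_sim, n_sub = idx_matrix.shape
    out = np.empty(n_sim)
    sx = np.empty(n_sub)
    sy = np.empty(n_sub)
    for s in range(n_sim):
        for k in range(n_sub):
            sx[k] = px[idx_matrix[s, k]]
            sy[k] = py[idx_matrix[s, k]]
        areas = _cell_areas_kernel(sx, sy, ring_x, ring_y)
        total = areas.sum()
        h = 0.0
        for k in range(n_sub):
            if areas[k] > 0.0:
                p = areas[k] / total
                h -= p * np.log(p)
        out[s] = h
    return out


def region_ring(region: Polygon) -> np.ndarray:
    """Exterior ring of a simple polygon as an (m, 2) CCW array (open)."""
    if not isinstance(region, Polygon):
        raise TypeError("region must be a shapely Polygon")
    if region.is_empty or region.area <= 0:
        raise ValueError("region polygon has zero area")
    if not region.is_simple or not region.is_valid:
        raise ValueError("region polygon must be simple and valid")
    if len(region.interiors) > 0:
        raise ValueError("region polygon must not contain holes")
    ring = np.asarray(orient(region, sign=1.0).exterior.coords, dtype=float)
    return ring[:-1]


def _dedupe_points(points: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Perturb exact duplicates by ``eps`` so every point owns a Voronoi cell."""
    pts = np.array(points, dtype=float)
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    seen = {}
    bumped = False
    for i in order:
        key = (pts[i, 0], pts[i, 1])
        if key in seen:
            seen[key] += 1
            pts[i, 0] += eps * seen[key]
            pts[i, 1] += eps * seen[key]
            bumped = True
        else:
            seen[key] = 0
    if bumped:
        warnings.warn(
            "duplicate point coordinates perturbed by 1e-9 um", stacklevel=3
        )
    return pts


def clipped_voronoi_areas(points: np.ndarray, region: Polygon) -> np.ndarray:
    """Areas of the Voronoi cells of ``points`` clipped to ``region``.

    Points must lie inside (or on the boundary of) the region.  Duplicate
    coordinates are perturbed by 1e-9 with a warning.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    if pts.shape[0] < 1:
        raise ValueError("need at least one point")
    if not np.all(np.isfinite(pts)):
        raise ValueError("point coordinates must be finite")
    inside = shapely.covers(
        shapely.buffer(region, 1e-6), shapely.points(pts[:, 0], pts[:, 1])
    )
    if not np.all(inside):
        bad = np.flatnonzero(~inside)
        raise ValueError(f"points outside region polygon at indices {bad.tolist()}")
    pts = _dedupe_points(pts)
    ring = region_ring(region)
    return _cell_areas_kernel(
        np.ascontiguousarray(pts[:, 0]),
        np.ascontiguousarray(pts[:, 1]),
        np.ascontiguousarray(ring[:, 0]),
        np.ascontiguousarray(ring[:, 1]),
    )


def polyline_distances(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Minimum Euclidean distance from each point to a polyline.

    Vectorized point-to-segment distance over all segments; a single-vertex
    polyline degenerates to point-to-point distance.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    line = np.atleast_2d(np.asarray(polyline, dtype=float))
    if line.shape[0] < 1:
        raise ValueError("polyline must contain at least one vertex")
    if line.shape[0] == 1:
        return np.hypot(pts[:, 0] - line[0, 0], pts[:, 1] - line[0, 1])
    a = line[:-1]  # (m, 2) segment starts
    d = line[1:] - a  # (m, 2) segment vectors
    seg_len2 = np.einsum("ij,ij->i", d, d)
    seg_len2 = np.where(seg_len2 == 0.0, 1.0, seg_len2)
    # (n, m) projection parameter, clamped to the segment
    w = pts[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("nmj,mj->nm", w, d) / seg_len2[None, :], 0.0, 1.0)
    closest = a[None, :, :] + t[:, :, None] * d[None, :, :]
    dist = np.hypot(
        pts[:, None, 0] - closest[:, :, 0], pts[:, None, 1] - closest[:, :, 1]
    )
    return dist.min(axis=1)
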