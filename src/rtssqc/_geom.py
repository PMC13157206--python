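"""Shared low-level geometry helpers (2D).

All functions operate on plain numpy arrays; the even-odd slice-region
helpers are backed by shapely.
"""
from __future__ import annotations

from functools import reduce

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.validation import make_valid

from .model import PlanarContour

_CHUNK = 4096  # points per block in pairwise distance kernels


def closed_segments(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Edge start/end arrays for a closed polygon (last vertex -> first)."""
    v = np.asarray(vertices, dtype=float)
    return v, np.roll(v, -1, axis=0)


def points_to_segments_distance(
    points: np.ndarray, seg_a: np.ndarray, seg_b: np.ndarray
) -> np.ndarray:
    """Minimum Euclidean distance from each point to a set of segments.

    Exact: perpendicular foot when it falls inside a segment, else the
    nearer endpoint.  ``points`` is (N, 2); segments are (M, 2) start/end
    pairs.  Returns (N,) distances.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    d = seg_b - seg_a  # (M, 2)
    dd = np.einsum("ij,ij->i", d, d)  # squared lengths
    dd_safe = np.where(dd > 0, dd, 1.0)
    out = np.empty(len(points))
    for lo in range(0, len(points), _CHUNK):
        p = points[lo : lo + _CHUNK]  # (n, 2)
        ap = p[:, None, :] - seg_a[None, :, :]  # (n, M, 2)
        t = np.clip(np.einsum("nmj,mj->nm", ap, d) / dd_safe, 0.0, 1.0)
        diff = ap - t[:, :, None] * d[None, :, :]
        dist2 = np.einsum("nmj,nmj->nm", diff, diff)
        out[lo : lo + _CHUNK] = np.sqrt(dist2.min(axis=1))
    return out


def contours_segment_arrays(contours: list[PlanarContour]) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated closed-edge arrays over several contours."""
    starts, ends = [], []
    for c in contours:
        a, b = closed_segments(c.vertices)
        starts.append(a)
        ends.append(b)
    return np.vstack(starts), np.vstack(ends)


def points_to_contours_distance(points: np.ndarray, contours: list[PlanarContour]) -> np.ndarray:
    """Distance from each point to the nearest closed polyline among ``contours``."""
    if not contours:
        return np.full(len(np.atleast_2d(points)), np.inf)
    seg_a, seg_b = contours_segment_arrays(contours)
    return points_to_segments_distance(points, seg_a, seg_b)


def subdivide_edges(vertices: np.ndarray, max_segment: float) -> tuple[np.ndarray, np.ndarray]:
    """Split each closed edge into sub-segments no longer than ``max_segment``.

    Returns (midpoints (K, 2), lengths (K,)).  Original vertices bound the
    sub-segments, so lengths sum exactly to the perimeter.
    """
    a, b = closed_segments(vertices)
    mids, lens = [], []
    edge_len = np.linalg.norm(b - a, axis=1)
    for pa, pb, length in zip(a, b, edge_len):
        if length == 0.0:
            continue
        n = max(1, int(np.ceil(length / max_segment)))
        t = (np.arange(n) + 0.5) / n
        mids.append(pa[None, :] + t[:, None] * (pb - pa)[None, :])
        lens.append(np.full(n, length / n))
    if not mids:
        return np.empty((0, 2)), np.empty(0)
    return np.vstack(mids), np.concatenate(lens)


def sample_boundary(vertices: np.ndarray, spacing: float) -> np.ndarray:
    """Arc-length samples of a closed polygon boundary at spacing <= ``spacing``.

    Every original vertex is included (corners are never skipped), with
    evenly spaced interior samples added per edge.
    """
    a, b = closed_segments(vertices)
    pts = []
    for pa, pb in zip(a, b):
        length = float(np.linalg.norm(pb - pa))
        n = max(1, int(np.ceil(length / spacing))) if length > 0 else 1
        t = np.arange(n) / n
        pts.append(pa[None, :] + t[:, None] * (pb - pa)[None, :])
    return np.vstack(pts)


def resample_closed_uniform(vertices: np.ndarray, target_spacing: float) -> np.ndarray:
    """Resample a closed polygon at uniform arc-length spacing.

    Starts from vertex 0 and walks the whole closed path; original corners
    are NOT guaranteed to be preserved.
    """
    v = np.asarray(vertices, dtype=float)
    closed = np.vstack([v, v[:1]])
    seg = np.diff(closed, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    total = float(seg_len.sum())
    if total == 0.0:
        return v.copy()
    n = max(3, int(round(total / target_spacing)))
    s = np.arange(n) * total / n
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_len) - 1)
    frac = (s - cum[idx]) / np.where(seg_len[idx] > 0, seg_len[idx], 1.0)
    return closed[idx] + frac[:, None] * seg[idx]


# ---------------------------------------------------------------------------
# shapely-backed even-odd slice regions
# ---------------------------------------------------------------------------

def _as_polygon(c: PlanarContour) -> Polygon | None:
    if c.n_vertices < 3:
        return None
    poly = Polygon(c.vertices)
    if not poly.is_valid:
        poly = make_valid(poly)
    return poly if poly.area > 0 else None


def slice_region(contours: list[PlanarContour]):
    """Even-odd (XOR) region of all contours on one slice.

    Overlapping contours cancel, so an opposite contour nested inside
    another subtracts area (hole semantics).  Returns a shapely geometry
    (possibly empty).
    """
    polys = [p for p in (_as_polygon(c) for c in contours) if p is not None]
    if not polys:
        return Polygon()
    return reduce(lambda a, b: a.symmetric_difference(b), polys)


def region_components(contours: list[PlanarContour]):
    """Connected components of the even-odd slice region as a list of
    shapely Polygons (each with its holes)."""
    region = slice_region(contours)
    if region.is_empty:
        return []
    if region.geom_type == "Polygon":
        return [region]
    return [g for g in region.geoms if g.geom_type == "Polygon" and g.area > 0]


def points_in_even_odd(
    x: np.ndarray, y: np.ndarray, contours: list[PlanarContour]
) -> np.ndarray:
    """Even-odd (crossing-parity) containment test for a batch of points.

    Strict interior: points exactly on a polygon edge count as outside.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    inside = np.zeros(x.shape, dtype=bool)
    for c in contours:
        if c.n_vertices < 3:
            continue
        poly = Polygon(c.vertices)
        inside ^= shapely.contains_xy(poly, x, y)
    return inside
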