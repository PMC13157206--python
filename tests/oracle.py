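"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately implemented with different algorithms from
the package under test: scalar per-edge distance loops, ray-casting
containment on sample grids, and dense point clouds with KD-tree nearest
neighbours instead of exact segment/triangle projections.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree


def point_segment_distance(px, py, ax, ay, bx, by) -> float:
    """Scalar point-to-segment distance (pure python math)."""
    dx, dy = bx - ax, by - ay
    dd = dx * dx + dy * dy
    if dd == 0.0:
        return math.hypot(px - ax, py - ay)
    t = ((px - ax) * dx + (py - ay) * dy) / dd
    t = min(1.0, max(0.0, t))
    return math.hypot(px - (ax + t * dx), py - (ay + t * dy))


def nearest_boundary_distance(p, contours) -> float:
    """Minimum distance from one point to any closed polyline (edge loop)."""
    best = math.inf
    for c in contours:
        v = c.vertices
        n = len(v)
        for i in range(n):
            ax, ay = v[i]
            bx, by = v[(i + 1) % n]
            best = min(best, point_segment_distance(p[0], p[1], ax, ay, bx, by))
    return best


def boundary_cloud(contours, spacing: float) -> np.ndarray:
    """Dense point cloud along closed boundaries (includes all vertices)."""
    pts = []
    for c in contours:
        v = c.vertices
        n = len(v)
        for i in range(n):
            a = v[i]
            b = v[(i + 1) % n]
            length = float(np.hypot(*(b - a)))
            k = max(1, int(math.ceil(length / spacing)))
            for j in range(k):
                pts.append(a + (j / k) * (b - a))
    return np.asarray(pts)


def slices_by_z(structure, decimals: int = 6) -> dict[float, list]:
    groups: dict[float, list] = {}
    for c in structure.contours:
        groups.setdefault(round(c.z, decimals), []).append(c)
    return groups


def napl_oracle(reference, test, tol_mm: float, n_per_slice: int = 10_000) -> float:
    """Dense-sampling estimate of the outside-tolerance perimeter fraction.

    Samples each reference slice's perimeter at uniform arc length
    (midpoint rule) and classifies every sample by scalar nearest-boundary
    distance against the matching test slice.
    """
    ref_slices = slices_by_z(reference)
    test_slices = slices_by_z(test)
    total = 0.0
    outside = 0.0
    for z, contours in ref_slices.items():
        others = test_slices.get(z, [])
        for c in contours:
            v = c.vertices
            n = len(v)
            lengths = [float(np.hypot(*(v[(i + 1) % n] - v[i]))) for i in range(n)]
            perim = sum(lengths)
            total += perim
            if not others:
                outside += perim
                continue
            per_edge = max(1, n_per_slice // n)
            for i in range(n):
                a, b = v[i], v[(i + 1) % n]
                for j in range(per_edge):
                    p = a + ((j + 0.5) / per_edge) * (b - a)
                    if nearest_boundary_distance(p, others) > tol_mm:
                        outside += lengths[i] / per_edge
    return outside / total


def ray_cast_inside(x: np.ndarray, y: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Crossing-number point-in-polygon test, vectorized over points."""
    inside = np.zeros(np.shape(x), dtype=bool)
    v = vertices
    n = len(v)
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        if y1 == y2:  # horizontal edge never crosses a horizontal ray
            continue
        crosses = ((y1 > y) != (y2 > y)) & (
            x < x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        )
        inside ^= crosses
    return inside


def even_odd_inside(x: np.ndarray, y: np.ndarray, contours) -> np.ndarray:
    inside = np.zeros(np.shape(x), dtype=bool)
    for c in contours:
        if len(c.vertices) >= 3:
            inside ^= ray_cast_inside(x, y, c.vertices)
    return inside


def vdsc_voxel_oracle(a, b, step: float = 0.25) -> float:
    """Volumetric Dice by point-grid counting at ``step`` mm resolution.

    Slice volumes are (inside count) * step^2 * dz-weight; dz cancels in
    the ratio for uniformly spaced slices, so it is omitted.
    """
    sa = slices_by_z(a)
    sb = slices_by_z(b)
    va = vb = vi = 0
    for z in sorted(set(sa) | set(sb)):
        ca = sa.get(z, [])
        cb = sb.get(z, [])
        pts = np.vstack(
            [c.vertices for c in ca] + [c.vertices for c in cb]
        )
        lo = pts.min(axis=0) - step
        hi = pts.max(axis=0) + step
        xs = np.arange(lo[0] + step / 2, hi[0], step)
        ys = np.arange(lo[1] + step / 2, hi[1], step)
        X, Y = np.meshgrid(xs, ys)
        in_a = even_odd_inside(X, Y, ca) if ca else np.zeros(X.shape, dtype=bool)
        in_b = even_odd_inside(X, Y, cb) if cb else np.zeros(X.shape, dtype=bool)
        va += int(in_a.sum())
        vb += int(in_b.sum())
        vi += int((in_a & in_b).sum())
    return 2.0 * vi / (va + vb)


def distance_aggregates_oracle(
    a, b, sample_spacing: float = 0.1, cloud_spacing: float = 0.02
) -> dict[str, float]:
    """2D distance family via dense point clouds and KD-tree lookups.

    Boundary samples at ``sample_spacing`` measured against the other
    boundary approximated by a cloud at ``cloud_spacing`` (quantization
    error <= cloud_spacing / 2).
    """
    sa = slices_by_z(a)
    sb = slices_by_z(b)
    pooled = []
    for z in sorted(set(sa) & set(sb)):
        ca, cb = sa[z], sb[z]
        cloud_a = boundary_cloud(ca, cloud_spacing)
        cloud_b = boundary_cloud(cb, cloud_spacing)
        tree_a = cKDTree(cloud_a)
        tree_b = cKDTree(cloud_b)
        d_ab, _ = tree_b.query(boundary_cloud(ca, sample_spacing))
        d_ba, _ = tree_a.query(boundary_cloud(cb, sample_spacing))
        pooled.extend([d_ab, d_ba])
    sample = np.concatenate(pooled)
    return {
        "hd2d_mm": float(sample.max()),
        "hd95_2d_mm": float(np.percentile(sample, 95)),
        "hd50_2d_mm": float(np.percentile(sample, 50)),
        "msd2d_mm": float(sample.mean()),
    }


def mesh_surface_cloud(mesh, spacing: float) -> np.ndarray:
    """Dense barycentric point samples of every triangle."""
    pts = [mesh.vertices]
    for tri in mesh.triangles:
        a, b, c = tri
        longest = max(
            np.linalg.norm(b - a), np.linalg.norm(c - a), np.linalg.norm(c - b)
        )
        n = max(2, int(math.ceil(longest / spacing)) + 1)
        for i in range(n + 1):
            for j in range(n + 1 - i):
                k = n - i - j
                pts.append([(i * a + j * b + k * c) / n])
    return np.vstack(pts)


def point_mesh_distance_oracle(points, mesh, spacing: float = 0.3) -> np.ndarray:
    """Nearest surface distance via a dense surface point cloud."""
    cloud = mesh_surface_cloud(mesh, spacing)
    d, _ = cKDTree(cloud).query(np.atleast_2d(points))
    return d
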