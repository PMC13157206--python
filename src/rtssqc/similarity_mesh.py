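"""Mesh-pathway measures: surface Dice at tolerance and 3D mean surface distance.

Structures are converted to an implicit representation at image resolution
(even-odd rasterization), a signed Euclidean distance field is computed,
and a triangle mesh is extracted at the zero level with the marching cubes
algorithm (sub-voxel placement).  Surface distances are evaluated at face
centroids with area weighting against the other mesh's triangles.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

from .errors import AnalysisError
from .model import ImageGrid, Structure
from .preprocess import group_by_slice
from .synthetic import _ensure_inplane_cover, rasterize_slice

_TOL_EPS = 1e-9  # absolute slack on tolerance comparisons (mm)


@dataclass
class TriangleMesh:
    vertices: np.ndarray  # (n, 3) mm
    faces: np.ndarray  # (m, 3) vertex indices

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("faces reference missing vertices")

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    @property
    def face_areas(self) -> np.ndarray:
        t = self.triangles
        cross = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    @property
    def face_centroids(self) -> np.ndarray:
        return self.triangles.mean(axis=1)

    @property
    def area(self) -> float:
        return float(self.face_areas.sum())

    def n_boundary_edges(self) -> int:
        """Edges used by exactly one face; 0 for a watertight mesh."""
        edges = np.sort(
            np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]),
            axis=1,
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return int((counts == 1).sum())

    def is_watertight(self) -> bool:
        return self.n_boundary_edges() == 0

    def export_obj(self, path) -> None:
        """Wavefront OBJ export for debugging."""
        with open(path, "w") as fh:
            for v in self.vertices:
                fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            for f in self.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def rasterize(s: Structure, grid: ImageGrid) -> tuple[np.ndarray, ImageGrid]:
    """Even-odd rasterization of a polygon stack onto voxel centers.

    Returns ``(volume, grid_used)`` with the volume indexed [iz, iy, ix].
    The grid is auto-expanded in-plane (preserving voxel alignment) when it
    does not cover the structure; voxel centers exactly on a polygon edge
    count as outside (strict interior).
    """
    grid = _ensure_inplane_cover(grid, s)
    volume = np.zeros((grid.shape[2], grid.shape[1], grid.shape[0]), dtype=bool)
    if s.is_empty:
        return volume, grid
    planes = grid.z_planes()
    for group in group_by_slice(s, 1e-6):
        iz = int(round((group.z - grid.origin[2]) / grid.dz))
        if not 0 <= iz < len(planes) or abs(planes[iz] - group.z) > grid.dz / 2 + 1e-9:
            continue
        volume[iz] |= rasterize_slice(group.contours, grid)
    return volume, grid


def extract_mesh(volume: np.ndarray, grid: ImageGrid) -> TriangleMesh:
    """Marching-cubes mesh of the zero level of the signed distance field.

    The signed Euclidean distance field (negative inside, positive outside)
    is computed at grid resolution on a zero-padded copy of the volume so
    the resulting mesh is closed; vertices are returned in patient mm.
    """
    volume = np.asarray(volume, dtype=bool)
    if not volume.any():
        raise AnalysisError("cannot extract a mesh from an empty volume")
    pad = 2
    padded = np.pad(volume, pad)
    sampling = (grid.dz, grid.dy, grid.dx)
    d_in = ndimage.distance_transform_edt(padded, sampling=sampling)
    d_out = ndimage.distance_transform_edt(~padded, sampling=sampling)
    signed = d_out - d_in
    verts, faces, _normals, _values = measure.marching_cubes(signed, level=0.0, spacing=sampling)
    # verts are (z, y, x) offsets in the padded frame
    offset = np.array(
        [
            grid.origin[2] - pad * grid.dz,
            grid.origin[1] - pad * grid.dy,
            grid.origin[0] - pad * grid.dx,
        ]
    )
    verts = verts + offset
    return TriangleMesh(vertices=verts[:, ::-1], faces=faces)


def structure_to_mesh(s: Structure, grid: ImageGrid) -> TriangleMesh:
    """Rasterize then extract: the full polygon-to-mesh pathway."""
    volume, used = rasterize(s, grid)
    return extract_mesh(volume, used)


# ---------------------------------------------------------------------------
# point-to-mesh distances
# ---------------------------------------------------------------------------

def _point_to_triangles(p: np.ndarray, tris: np.ndarray) -> float:
    """Exact minimum distance from one point to a set of triangles.

    The closest point on a triangle is either the in-plane projection (when
    its barycentric coordinates are non-negative) or lies on one of the
    three edge segments.
    """
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    n = np.cross(b - a, c - a)
    nn = np.einsum("ij,ij->i", n, n)
    ok = nn > 0
    best = np.inf
    if ok.any():
        t = np.einsum("ij,ij->i", p - a[ok], n[ok]) / nn[ok]
        proj = p - t[:, None] * n[ok]
        # barycentric test of the projection
        v0 = b[ok] - a[ok]
        v1 = c[ok] - a[ok]
        v2 = proj - a[ok]
        d00 = np.einsum("ij,ij->i", v0, v0)
        d01 = np.einsum("ij,ij->i", v0, v1)
        d11 = np.einsum("ij,ij->i", v1, v1)
        d20 = np.einsum("ij,ij->i", v2, v0)
        d21 = np.einsum("ij,ij->i", v2, v1)
        denom = d00 * d11 - d01 * d01
        denom = np.where(np.abs(denom) > 0, denom, 1.0)
        v = (d11 * d20 - d01 * d21) / denom
        w = (d00 * d21 - d01 * d20) / denom
        inside = (v >= -1e-12) & (w >= -1e-12) & (v + w <= 1 + 1e-12)
        if inside.any():
            best = float(np.linalg.norm((p - proj)[inside], axis=1).min())

    def seg_min(sa: np.ndarray, sb: np.ndarray) -> float:
        d = sb - sa
        dd = np.einsum("ij,ij->i", d, d)
        dd = np.where(dd > 0, dd, 1.0)
        t = np.clip(np.einsum("ij,ij->i", p - sa, d) / dd, 0.0, 1.0)
        diff = p - (sa + t[:, None] * d)
        return float(np.sqrt(np.einsum("ij,ij->i", diff, diff).min()))

    best = min(best, seg_min(a, b), seg_min(b, c), seg_min(c, a))
    return best


def point_mesh_distance(points: np.ndarray, mesh: TriangleMesh) -> np.ndarray:
    """Nearest distance from each point to the mesh surface (point-to-triangle).

    A nearest-vertex query gives an upper bound per point; only triangles
    whose centroid lies within that bound (plus the largest
    centroid-to-corner radius) can improve it, so the exact test runs on a
    small candidate set.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tris = mesh.triangles
    if len(tris) == 0:
        raise AnalysisError("mesh has no faces")
    centroids = mesh.face_centroids
    r_max = float(np.linalg.norm(tris - centroids[:, None, :], axis=2).max())
    d_vert, _ = cKDTree(mesh.vertices).query(points)
    ctree = cKDTree(centroids)
    candidates = ctree.query_ball_point(points, d_vert + r_max + 1e-9)
    out = np.empty(len(points))
    for i, (p, cand) in enumerate(zip(points, candidates)):
        if cand:
            out[i] = min(d_vert[i], _point_to_triangles(p, tris[cand]))
        else:
            out[i] = d_vert[i]
    return out


def _check_meshes(mesh_a: TriangleMesh, mesh_b: TriangleMesh) -> None:
    if mesh_a.area <= 0 or mesh_b.area <= 0:
        raise AnalysisError("zero-area mesh: surface measures undefined")


def sdsc(mesh_a: TriangleMesh, mesh_b: TriangleMesh, tol_mm: float) -> float:
    """Surface Dice coefficient at a distance tolerance.

    Area-weighted fraction of the combined surfaces lying within ``tol_mm``
    of the other surface; per-face distance is evaluated at the face
    centroid against the other mesh's triangles.
    """
    if tol_mm < 0:
        raise ValueError("tol_mm must be >= 0")
    _check_meshes(mesh_a, mesh_b)
    area_a = mesh_a.face_areas
    area_b = mesh_b.face_areas
    d_ab = point_mesh_distance(mesh_a.face_centroids, mesh_b)
    d_ba = point_mesh_distance(mesh_b.face_centroids, mesh_a)
    within = float(area_a[d_ab <= tol_mm + _TOL_EPS].sum() + area_b[d_ba <= tol_mm + _TOL_EPS].sum())
    return within / float(area_a.sum() + area_b.sum())


def msd3d(mesh_a: TriangleMesh, mesh_b: TriangleMesh) -> float:
    """Symmetrized area-weighted mean surface distance in 3D (mm)."""
    _check_meshes(mesh_a, mesh_b)
    area_a = mesh_a.face_areas
    area_b = mesh_b.face_areas
    d_ab = point_mesh_distance(mesh_a.face_centroids, mesh_b)
    d_ba = point_mesh_distance(mesh_b.face_centroids, mesh_a)
    num = float((area_a * d_ab).sum() + (area_b * d_ba).sum())
    return num / float(area_a.sum() + area_b.sum())


def surface_measures(
    mesh_a: TriangleMesh, mesh_b: TriangleMesh, tolerances_mm: list[float]
) -> tuple[dict[float, float], float]:
    """sDSC at each tolerance plus 3DMSD, sharing the distance evaluations."""
    _check_meshes(mesh_a, mesh_b)
    area_a = mesh_a.face_areas
    area_b = mesh_b.face_areas
    d_ab = point_mesh_distance(mesh_a.face_centroids, mesh_b)
    d_ba = point_mesh_distance(mesh_b.face_centroids, mesh_a)
    total = float(area_a.sum() + area_b.sum())
    out = {}
    for tol in tolerances_mm:
        within = float(
            area_a[d_ab <= tol + _TOL_EPS].sum() + area_b[d_ba <= tol + _TOL_EPS].sum()
        )
        out[tol] = within / total
    mean = float((area_a * d_ab).sum() + (area_b * d_ba).sum()) / total
    return out, mean
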