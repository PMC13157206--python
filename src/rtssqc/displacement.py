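"""Vertex-displacement analysis between an original and a re-exported structure.

For every original polygon vertex, the distance to the nearest location on
the re-exported contour (closest point on the closed polyline, not nearest
vertex) is computed slice-by-slice in 2D.  Summaries include the mean and
maximum, a cumulative curve in voxel-relative units, vertex-count
bookkeeping and a topology-change flag.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _geom
from .errors import AnalysisError
from .model import ImageGrid, PlanarContour, Structure
from .preprocess import match_slices


def point_to_polyline_distance(p, c: PlanarContour) -> float:
    """Exact minimum distance from a point to a closed polygon boundary.

    The nearest location is the perpendicular foot when it falls inside an
    edge segment, else the nearer endpoint.
    """
    if c.n_vertices < 3:
        raise AnalysisError("contour must have at least 3 vertices")
    seg_a, seg_b = _geom.closed_segments(c.vertices)
    return float(_geom.points_to_segments_distance(np.asarray(p, dtype=float), seg_a, seg_b)[0])


@dataclass
class DisplacementSummary:
    """Displacement of one structure's vertices after re-export."""

    mean_mm: float
    max_mm: float
    n_vertices_original: int
    n_vertices_reexported: int
    cumulative: list[tuple[float, float]]  # (distance in voxels, fraction <= distance)
    topology_changed: bool
    per_slice_region_delta: list[tuple[float, int]]  # (z, region count delta)
    n_unmatched_vertices: int = 0
    distances_mm: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def fraction_below(self, distance_voxels: float) -> float:
        """Fraction of original vertices displaced by <= ``distance_voxels``
        (unmatched-slice vertices count as displaced beyond any distance)."""
        total = self.n_vertices_original
        if total == 0:
            return 1.0
        voxels = np.asarray([d for d, _ in self.cumulative])
        fracs = np.asarray([f for _, f in self.cumulative])
        below = fracs[voxels <= distance_voxels + 1e-12]
        return float(below[-1]) if len(below) else 0.0


def _directional_vertex_distances(
    original: Structure, reexported: Structure, z_tol: float
) -> tuple[np.ndarray, int]:
    """Per-vertex nearest distances original -> re-exported, slice-matched.

    Vertices on original slices with no re-exported counterpart get +inf.
    Returns (distances over all original vertices, count of +inf).
    """
    dists = []
    n_inf = 0
    for _z, ca, cb in match_slices(original, reexported, z_tol):
        if not ca:
            continue
        pts = np.vstack([c.vertices for c in ca])
        if not cb:
            dists.append(np.full(len(pts), np.inf))
            n_inf += len(pts)
            continue
        dists.append(_geom.points_to_contours_distance(pts, cb))
    if not dists:
        return np.empty(0), 0
    return np.concatenate(dists), n_inf


def cumulative_curve(
    distances_mm: np.ndarray, voxel_size_mm: float, n_total: int | None = None
) -> list[tuple[float, float]]:
    """Cumulative distribution of displacements in voxel-relative units.

    ``n_total`` sets the denominator (defaults to the number of finite
    distances); with sentinel vertices present the curve tops out below 1.
    """
    finite = np.sort(distances_mm[np.isfinite(distances_mm)])
    if n_total is None:
        n_total = len(finite)
    if n_total == 0:
        return []
    voxels = finite / voxel_size_mm
    fracs = np.arange(1, len(finite) + 1) / n_total
    # collapse ties so the curve is a function of distance
    keep = np.concatenate([voxels[1:] != voxels[:-1], [True]]) if len(voxels) else []
    return [(float(v), float(f)) for v, f in zip(voxels[keep], fracs[keep])]


def detect_topology_change(
    original: Structure,
    reexported: Structure,
    grid: ImageGrid,
    asym_threshold_voxels: float = 2.0,
    z_tol: float | None = None,
) -> tuple[bool, list[tuple[float, int]]]:
    """Flag topology changes between cleaned structures.

    True when (a) the per-slice connected-region counts differ on any
    matched slice, or (b) the directional maximum displacement in one
    direction exceeds ``asym_threshold_voxels`` while the other direction
    does not (large one-way distance without a counterpart indicates a
    removed or added region).
    """
    z_tol = grid.dz / 10.0 if z_tol is None else z_tol
    deltas: list[tuple[float, int]] = []
    count_mismatch = False
    for z, ca, cb in match_slices(original, reexported, z_tol):
        na = len(_geom.region_components(ca)) if ca else 0
        nb = len(_geom.region_components(cb)) if cb else 0
        deltas.append((z, nb - na))
        if na != nb:
            count_mismatch = True

    d_ab, _ = _directional_vertex_distances(original, reexported, z_tol)
    d_ba, _ = _directional_vertex_distances(reexported, original, z_tol)
    thr = asym_threshold_voxels * grid.in_plane_voxel_size

    def dir_max(d: np.ndarray) -> float:
        finite = d[np.isfinite(d)]
        return float(finite.max()) if len(finite) else 0.0

    big_ab = dir_max(d_ab) > thr or np.isinf(d_ab).any()
    big_ba = dir_max(d_ba) > thr or np.isinf(d_ba).any()
    asymmetric = big_ab != big_ba
    return bool(count_mismatch or asymmetric), deltas


def displacement_summary(
    original: Structure,
    reexported: Structure,
    grid: ImageGrid,
    z_tol: float | None = None,
    asym_threshold_voxels: float = 2.0,
) -> DisplacementSummary:
    """Quantify how far the re-exported contour moved from the original.

    Distances are computed strictly in 2D within z-matched slices.  Original
    vertices on slices absent from the re-export are excluded from the mean
    and maximum but keep the cumulative curve below 1 and feed the topology
    flag.  The cumulative curve is expressed in units of the in-plane voxel
    size.
    """
    z_tol = grid.dz / 10.0 if z_tol is None else z_tol
    dists, n_inf = _directional_vertex_distances(original, reexported, z_tol)
    if len(dists) == 0:
        raise AnalysisError(
            f"no matching slices between {original.name!r} and {reexported.name!r}"
        )
    finite = dists[np.isfinite(dists)]
    if len(finite) == 0:
        raise AnalysisError(
            f"no matching slices between {original.name!r} and {reexported.name!r}"
        )
    mean_mm = float(finite.mean())
    max_mm = float(finite.max())
    topology, deltas = detect_topology_change(
        original, reexported, grid, asym_threshold_voxels, z_tol
    )
    return DisplacementSummary(
        mean_mm=mean_mm,
        max_mm=max_mm,
        n_vertices_original=original.n_vertices,
        n_vertices_reexported=reexported.n_vertices,
        cumulative=cumulative_curve(dists, grid.in_plane_voxel_size, n_total=len(dists)),
        topology_changed=topology,
        per_slice_region_delta=deltas,
        n_unmatched_vertices=n_inf,
        distances_mm=dists,
    )


# ---------------------------------------------------------------------------
# CSV export
# ---------------------------------------------------------------------------

def summaries_to_frame(rows: dict[str, DisplacementSummary]) -> pd.DataFrame:
    """One row per structure: scalar displacement summary fields."""
    records = []
    for key, s in rows.items():
        records.append(
            {
                "structure": key,
                "mean_mm": s.mean_mm,
                "max_mm": s.max_mm,
                "n_vertices_original": s.n_vertices_original,
                "n_vertices_reexported": s.n_vertices_reexported,
                "n_unmatched_vertices": s.n_unmatched_vertices,
                "topology_changed": s.topology_changed,
            }
        )
    return pd.DataFrame.from_records(records)


def curves_to_frame(rows: dict[str, DisplacementSummary]) -> pd.DataFrame:
    """Long-form cumulative curves: one row per (structure, distance)."""
    records = []
    for key, s in rows.items():
        for voxels, frac in s.cumulative:
            records.append(
                {"structure": key, "distance_voxels": voxels, "fraction": frac}
            )
    return pd.DataFrame.from_records(records)
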