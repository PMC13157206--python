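"""Similarity measures computed directly on the polygon stacks.

Covers the normalised added path length (nAPL) at voxel-relative
tolerances, the volumetric Dice coefficient by exact polygon clipping, and
the 2D boundary-distance family (2DHD, 95%2DHD, 50%2DHD, 2DMSD) from
pooled bidirectional boundary samples.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _geom
from .errors import AnalysisError
from .model import ImageGrid, PlanarContour, Structure
from .preprocess import match_slices

DEFAULT_TOLERANCE_FRACTIONS = (0.01, 0.1, 0.5, 1.0, 2.0, 3.0)
DEFAULT_SAMPLE_SPACING = 0.1  # mm, boundary sampling for the distance family
MIN_SEGMENT = 0.05  # mm, floor for nAPL edge subdivision


@dataclass(frozen=True)
class ToleranceSpec:
    """Tolerances expressed as fractions of the in-plane voxel size."""

    fractions_of_voxel: tuple[float, ...] = DEFAULT_TOLERANCE_FRACTIONS

    def __post_init__(self) -> None:
        f = self.fractions_of_voxel
        if not f or min(f) <= 0:
            raise ValueError("tolerance fractions must be positive")
        if any(b <= a for a, b in zip(f, f[1:])):
            raise ValueError("tolerance fractions must be strictly increasing")

    def resolved_mm(self, grid: ImageGrid) -> list[float]:
        v = grid.in_plane_voxel_size
        return [f * v for f in self.fractions_of_voxel]


@dataclass
class Distances2D:
    """Pooled bidirectional 2D boundary-distance sample and aggregates."""

    hd2d_mm: float
    hd95_2d_mm: float
    hd50_2d_mm: float
    msd2d_mm: float
    dir_max_ab_mm: float
    dir_max_ba_mm: float
    n_samples: int
    n_unmatched_ab: int = 0
    n_unmatched_ba: int = 0
    pooled_mm: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


@dataclass
class MeasureSet:
    """All eight similarity measures for one structure pair."""

    napl: dict[float, float]  # tolerance fraction -> [0, 1]
    vdsc: float
    hd2d_mm: float
    hd95_2d_mm: float
    hd50_2d_mm: float
    msd2d_mm: float
    sdsc: dict[float, float]  # tolerance fraction -> [0, 1]
    msd3d_mm: float

    def as_row(self) -> dict:
        row = {
            "vdsc": self.vdsc,
            "hd2d_mm": self.hd2d_mm,
            "hd95_2d_mm": self.hd95_2d_mm,
            "hd50_2d_mm": self.hd50_2d_mm,
            "msd2d_mm": self.msd2d_mm,
            "msd3d_mm": self.msd3d_mm,
        }
        for frac, v in self.napl.items():
            row[f"napl@{frac:g}"] = v
        for frac, v in self.sdsc.items():
            row[f"sdsc@{frac:g}"] = v
        return row


def path_length(c: PlanarContour) -> float:
    """Closed-cycle perimeter in mm."""
    return c.perimeter


def napl_sweep(
    reference: Structure,
    test: Structure,
    tols_mm: list[float],
    z_tol: float = 1e-3,
    max_segment: float | None = None,
) -> list[float]:
    """Normalised added path length at several distance tolerances.

    Fraction of the reference's total perimeter (over all slices) lying
    farther than the tolerance from the test contours on the matching
    slice: 0 means within tolerance everywhere, 1 outside everywhere.
    Each reference edge is subdivided into sub-segments no longer than
    ``max_segment`` (default: the smallest tolerance / 4, with a 0.05 mm
    floor) and classified by the distance of its midpoint; reference
    slices with no matching test slice count as fully outside.  The
    subdivision and distance evaluations are shared across the sweep.
    """
    if not tols_mm or min(tols_mm) < 0:
        raise ValueError("tolerances must be >= 0")
    if reference.is_empty:
        raise AnalysisError("empty reference structure after cleaning")
    if max_segment is None:
        max_segment = max(min(tols_mm) / 4.0, MIN_SEGMENT)
    total = 0.0
    outside = np.zeros(len(tols_mm))
    tols = np.asarray(tols_mm)
    for _z, ref_contours, test_contours in match_slices(reference, test, z_tol):
        if not ref_contours:
            continue
        for c in ref_contours:
            mids, lens = _geom.subdivide_edges(c.vertices, max_segment)
            total += float(lens.sum())
            if not test_contours:
                outside += float(lens.sum())
                continue
            d = _geom.points_to_contours_distance(mids, test_contours)
            outside += (lens[None, :] * (d[None, :] > tols[:, None])).sum(axis=1)
    if total == 0.0:
        raise AnalysisError("reference structure has zero total path length")
    return [float(v) for v in outside / total]


def napl(
    reference: Structure,
    test: Structure,
    tol_mm: float,
    z_tol: float = 1e-3,
    max_segment: float | None = None,
) -> float:
    """Normalised added path length at one tolerance; see :func:`napl_sweep`."""
    return napl_sweep(reference, test, [tol_mm], z_tol, max_segment)[0]


def _slice_volumes(
    matched: list[tuple[float, list[PlanarContour], list[PlanarContour]]], dz: float
) -> tuple[float, float, float]:
    """(volume A, volume B, intersection volume) by exact polygon clipping."""
    va = vb = vi = 0.0
    for _z, ca, cb in matched:
        ra = _geom.slice_region(ca) if ca else None
        rb = _geom.slice_region(cb) if cb else None
        if ra is not None:
            va += ra.area * dz
        if rb is not None:
            vb += rb.area * dz
        if ra is not None and rb is not None and not ra.is_empty and not rb.is_empty:
            vi += ra.intersection(rb).area * dz
    return va, vb, vi


def vdsc(a: Structure, b: Structure, grid: ImageGrid, z_tol: float | None = None) -> float:
    """Volumetric Dice coefficient 2 V(A∩B) / (V(A) + V(B)).

    Per-slice areas and intersection areas use exact polygon clipping with
    even-odd hole handling; each slice contributes area × dz.  Slices
    present in only one structure contribute to that volume only.
    """
    z_tol = grid.dz / 10.0 if z_tol is None else z_tol
    matched = match_slices(a, b, z_tol)
    va, vb, vi = _slice_volumes(matched, grid.dz)
    if va + vb == 0.0:
        raise AnalysisError("both structures enclose zero volume; vDSC undefined")
    return 2.0 * vi / (va + vb)


def distances_2d(
    a: Structure,
    b: Structure,
    z_tol: float = 1e-3,
    sample_spacing: float = DEFAULT_SAMPLE_SPACING,
) -> Distances2D:
    """Slice-wise bidirectional boundary distances and their aggregates.

    Both boundaries are resampled at arc-length spacing <= ``sample_spacing``
    (original vertices always kept); each sample's nearest distance to the
    other structure's polylines on that slice is pooled over all slices and
    both directions.  hd2d/hd95/hd50/msd2d are the max, 95th percentile,
    median and mean of the pooled sample.  Samples on slices with no
    counterpart are +inf sentinels: excluded from the aggregates (with a
    warning) but reported, and they drive directional maxima to +inf.
    """
    pooled: list[np.ndarray] = []
    dir_ab: list[np.ndarray] = []
    dir_ba: list[np.ndarray] = []
    for _z, ca, cb in match_slices(a, b, z_tol):
        for src, dst, bucket in ((ca, cb, dir_ab), (cb, ca, dir_ba)):
            if not src:
                continue
            pts = np.vstack([_geom.sample_boundary(c.vertices, sample_spacing) for c in src])
            d = (
                _geom.points_to_contours_distance(pts, dst)
                if dst
                else np.full(len(pts), np.inf)
            )
            bucket.append(d)
            pooled.append(d)
    if not pooled:
        raise AnalysisError("no boundary samples: both structures empty")
    sample = np.concatenate(pooled)
    finite = sample[np.isfinite(sample)]
    n_inf_ab = int(sum(np.isinf(d).sum() for d in dir_ab))
    n_inf_ba = int(sum(np.isinf(d).sum() for d in dir_ba))
    if len(finite) < len(sample):
        warnings.warn(
            f"{len(sample) - len(finite)} boundary samples on unmatched slices "
            "excluded from 2D distance aggregates",
            stacklevel=2,
        )
    if len(finite) == 0:
        raise AnalysisError("no matched slices: 2D distances undefined")

    def dir_max(parts: list[np.ndarray]) -> float:
        if not parts:
            return 0.0
        return float(np.concatenate(parts).max())

    return Distances2D(
        hd2d_mm=float(finite.max()),
        hd95_2d_mm=float(np.percentile(finite, 95)),
        hd50_2d_mm=float(np.percentile(finite, 50)),
        msd2d_mm=float(finite.mean()),
        dir_max_ab_mm=dir_max(dir_ab),
        dir_max_ba_mm=dir_max(dir_ba),
        n_samples=len(sample),
        n_unmatched_ab=n_inf_ab,
        n_unmatched_ba=n_inf_ba,
        pooled_mm=sample,
    )
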