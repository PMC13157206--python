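"""Core data model: planar contours, structures and the image grid.

Coordinates are patient millimetres throughout.  Contours are closed planar
polygons; the closing vertex is implicit (never stored twice).  Voxel-index
coordinates never appear in contours — conversion to grid indices happens
only inside rasterization.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

CLOSED_PLANAR = "CLOSED_PLANAR"


@dataclass
class PlanarContour:
    """One closed planar polygon at a fixed z.

    Parameters
    ----------
    vertices:
        ``(n, 2)`` array of (x, y) positions in mm, patient coordinates.
        The polygon is implicitly closed: the last vertex connects back to
        the first.
    z:
        Slice position in mm (stored once for the whole contour).
    geometric_type:
        DICOM contour geometric type label; only ``CLOSED_PLANAR`` is
        produced by this package.
    """

    vertices: np.ndarray
    z: float
    geometric_type: str = CLOSED_PLANAR

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        self.z = float(self.z)

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def signed_area(self) -> float:
        """Shoelace area; sign encodes orientation (CCW positive)."""
        v = self.vertices
        if len(v) < 3:
            return 0.0
        x, y = v[:, 0], v[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def area(self) -> float:
        return abs(self.signed_area)

    @property
    def perimeter(self) -> float:
        """Closed-cycle path length in mm."""
        v = self.vertices
        if len(v) < 2:
            return 0.0
        return float(np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1).sum())

    def translated(self, dx: float = 0.0, dy: float = 0.0, dz: float = 0.0) -> "PlanarContour":
        return PlanarContour(self.vertices + np.array([dx, dy]), self.z + dz, self.geometric_type)

    def points3d(self) -> np.ndarray:
        """``(n, 3)`` array of (x, y, z) triplets."""
        out = np.empty((self.n_vertices, 3))
        out[:, :2] = self.vertices
        out[:, 2] = self.z
        return out


@dataclass
class Structure:
    """A named stack of planar contours.

    Multiple contours may share one z (disconnected regions or holes).
    """

    name: str
    contours: list[PlanarContour] = field(default_factory=list)
    frame_of_reference: str = ""

    @property
    def n_vertices(self) -> int:
        return sum(c.n_vertices for c in self.contours)

    @property
    def n_contours(self) -> int:
        return len(self.contours)

    @property
    def is_empty(self) -> bool:
        return not self.contours

    def z_values(self) -> np.ndarray:
        return np.array(sorted({c.z for c in self.contours}))

    def sorted_by_z(self) -> "Structure":
        return replace(self, contours=sorted(self.contours, key=lambda c: c.z))

    def translated(self, dx: float = 0.0, dy: float = 0.0, dz: float = 0.0) -> "Structure":
        return replace(self, contours=[c.translated(dx, dy, dz) for c in self.contours])

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) corners of the axis-aligned bounding box, (x, y, z)."""
        if self.is_empty:
            raise ValueError(f"structure {self.name!r} has no contours")
        pts = np.vstack([c.points3d() for c in self.contours])
        return pts.min(axis=0), pts.max(axis=0)


@dataclass(frozen=True)
class ImageGrid:
    """Geometry of the image grid a structure set refers to.

    ``origin`` is the patient-mm position of the *center* of voxel
    (0, 0, 0); voxel centers sit at ``origin + index * spacing``.  The
    in-plane voxel size defines the unit for voxel-relative tolerances and
    cumulative displacement curves.
    """

    dx: float
    dy: float
    dz: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shape: tuple[int, int, int] = (1, 1, 1)  # (nx, ny, nz)

    def __post_init__(self) -> None:
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("grid spacings must be positive")
        if min(self.shape) < 1:
            raise ValueError("grid shape must be at least 1 voxel per axis")

    @property
    def in_plane_voxel_size(self) -> float:
        """Normalizer for tolerances: min(dx, dy) when anisotropic."""
        return min(self.dx, self.dy)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.dx, self.dy, self.dz)

    def x_centers(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.shape[0]) * self.dx

    def y_centers(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.shape[1]) * self.dy

    def z_planes(self) -> np.ndarray:
        return self.origin[2] + np.arange(self.shape[2]) * self.dz

    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer (min, max) corners including the half-voxel margin."""
        lo = np.array(self.origin) - 0.5 * np.array(self.spacing)
        hi = lo + np.array(self.shape) * np.array(self.spacing)
        return lo, hi

    def contains(self, structure: Structure) -> bool:
        if structure.is_empty:
            return True
        lo, hi = self.extent()
        smin, smax = structure.bounds()
        return bool(np.all(smin >= lo - 1e-9) and np.all(smax <= hi + 1e-9))

    def check_contains(self, structure: Structure) -> None:
        """Warn (not error) when contours fall outside the grid extents."""
        if not self.contains(structure):
            warnings.warn(
                f"structure {structure.name!r} extends beyond the grid extents",
                stacklevel=3,
            )

    @classmethod
    def covering(
        cls,
        structures: Sequence[Structure] | Iterable[Structure],
        dx: float = 1.0,
        dy: float = 1.0,
        dz: float = 2.5,
        pad_voxels: int = 3,
    ) -> "ImageGrid":
        """Build a grid that covers all given structures with a margin.

        In-plane voxel centers are anchored half a voxel off the combined
        lower bound, so the boundary of an axis-aligned shape whose width
        is a multiple of the spacing falls midway between voxel centers
        (never exactly on one); z planes are anchored on the lowest contour
        plane so existing slices map exactly onto grid planes.
        """
        structures = [s for s in structures if not s.is_empty]
        if not structures:
            raise ValueError("no non-empty structures to cover")
        mins = np.min([s.bounds()[0] for s in structures], axis=0)
        maxs = np.max([s.bounds()[1] for s in structures], axis=0)

        ox = mins[0] - (pad_voxels - 0.5) * dx
        oy = mins[1] - (pad_voxels - 0.5) * dy
        oz = mins[2] - pad_voxels * dz
        nx = int(math.ceil((maxs[0] - ox) / dx)) + 1 + pad_voxels
        ny = int(math.ceil((maxs[1] - oy) / dy)) + 1 + pad_voxels
        nz = int(round((maxs[2] - mins[2]) / dz)) + 1 + 2 * pad_voxels
        return cls(dx, dy, dz, (ox, oy, oz), (nx, ny, nz))

    def to_dict(self) -> dict:
        return {
            "dx": self.dx,
            "dy": self.dy,
            "dz": self.dz,
            "origin": list(self.origin),
            "shape": list(self.shape),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ImageGrid":
        return cls(
            dx=float(d["dx"]),
            dy=float(d["dy"]),
            dz=float(d["dz"]),
            origin=tuple(float(v) for v in d.get("origin", (0, 0, 0))),
            shape=tuple(int(v) for v in d.get("shape", (1, 1, 1))),
        )
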