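"""Analytic test structures and a simulator of re-export behaviours.

Generates the six analytic reference/test pairs (sparse and dense cuboids
and octahedra), lung-like multi-region fixtures for topology tests, and
perturbations that emulate what contour-editing systems do to a structure
set on a load/save round trip: coordinate precision truncation, boundary
resampling, 2D/3D mask round trips, small-region removal, and vertex
subsampling/densification.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import ndimage
from shapely.geometry import Point
from skimage import measure

from . import _geom
from .errors import ConfigError, ParameterError
from .model import ImageGrid, PlanarContour, Structure
from .preprocess import group_by_slice

DEFAULT_AREA_EPS = 1e-6  # mm^2; apex slices below this are omitted

PERTURBATION_MODES = (
    "truncate_precision",
    "resample_path",
    "mask_roundtrip_2d",
    "mask_roundtrip_3d",
    "drop_small_regions",
    "subsample_vertices",
    "densify_vertices",
)


@dataclass(frozen=True)
class ShapeSpec:
    """Parameters of one analytic shape.

    ``size`` is the full edge length for cuboids (scalar cube or per-axis
    triple) and the half-diagonal for octahedra.
    """

    kind: str  # cuboid | octahedron | multi_region
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    size: float | tuple[float, float, float] = 50.0
    sampling: str = "sparse"  # sparse | dense
    vertex_spacing: float = 1.0
    dz: float = 2.5
    satellite_size: float = 6.0  # multi_region: satellite cube edge, mm
    separation: float = 30.0  # multi_region: center-to-center x offset, mm
    area_eps: float = DEFAULT_AREA_EPS

    def __post_init__(self) -> None:
        sizes = self.size if isinstance(self.size, tuple) else (self.size,)
        if min(sizes) <= 0:
            raise ParameterError("size must be positive")
        if self.sampling not in ("sparse", "dense"):
            raise ParameterError(f"unknown sampling {self.sampling!r}")
        if self.sampling == "dense" and self.vertex_spacing <= 0:
            raise ParameterError("vertex_spacing must be positive in dense mode")
        if self.dz <= 0:
            raise ParameterError("dz must be positive")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "center": list(self.center),
            "size": list(self.size) if isinstance(self.size, tuple) else self.size,
            "sampling": self.sampling,
            "vertex_spacing": self.vertex_spacing,
            "dz": self.dz,
        }


def _slice_positions(z_center: float, height: float, dz: float) -> np.ndarray:
    """End-slice convention: both z extremes inclusive, floor(H/dz)+1 slices."""
    n = int(math.floor(height / dz + 1e-9)) + 1
    return z_center - height / 2.0 + np.arange(n) * dz


def _ring(corners: np.ndarray, spacing: float | None) -> np.ndarray:
    """Polygon from corner list; dense mode adds points every ``spacing``
    along the perimeter with corners always included."""
    if spacing is None:
        return corners.copy()
    pts = []
    nxt = np.roll(corners, -1, axis=0)
    for pa, pb in zip(corners, nxt):
        length = float(np.linalg.norm(pb - pa))
        k = max(1, int(math.ceil(length / spacing - 1e-9)))
        t = np.arange(k) / k
        pts.append(pa[None, :] + t[:, None] * (pb - pa)[None, :])
    return np.vstack(pts)


def make_cuboid(spec: ShapeSpec) -> Structure:
    """Axis-aligned cuboid: one square/rectangular contour per slice.

    Sparse sampling gives exactly the 4 corner vertices per slice; dense
    sampling adds vertices every ``vertex_spacing`` along the perimeter.
    """
    if spec.kind != "cuboid":
        raise ParameterError(f"make_cuboid got kind {spec.kind!r}")
    sx, sy, sz = (
        spec.size if isinstance(spec.size, tuple) else (spec.size, spec.size, spec.size)
    )
    cx, cy, cz = spec.center
    spacing = None
    if spec.sampling == "dense":
        if spec.vertex_spacing > min(sx, sy):
            raise ParameterError("vertex_spacing exceeds the side length")
        spacing = spec.vertex_spacing
    corners = np.array(
        [
            [cx - sx / 2, cy - sy / 2],
            [cx + sx / 2, cy - sy / 2],
            [cx + sx / 2, cy + sy / 2],
            [cx - sx / 2, cy + sy / 2],
        ]
    )
    ring = _ring(corners, spacing)
    contours = [PlanarContour(ring, z) for z in _slice_positions(cz, sz, spec.dz)]
    return Structure(name="cuboid", contours=contours)


def make_octahedron(spec: ShapeSpec) -> Structure:
    """Regular axis-aligned octahedron (per-slice diamond cross-sections).

    The diamond half-width at height offset h is ``a - |h|`` for
    half-diagonal a; apex slices whose area falls below ``area_eps`` are
    omitted as degenerate.
    """
    if spec.kind != "octahedron":
        raise ParameterError(f"make_octahedron got kind {spec.kind!r}")
    a = float(spec.size if not isinstance(spec.size, tuple) else spec.size[0])
    cx, cy, cz = spec.center
    contours = []
    for z in _slice_positions(cz, 2 * a, spec.dz):
        w = a - abs(z - cz)
        if 2 * w * w < spec.area_eps:  # diamond area = 2 w^2
            continue
        corners = np.array([[cx + w, cy], [cx, cy + w], [cx - w, cy], [cx, cy - w]])
        spacing = spec.vertex_spacing if spec.sampling == "dense" else None
        contours.append(PlanarContour(_ring(corners, spacing), z))
    return Structure(name="octahedron", contours=contours)


def make_multi_region(spec: ShapeSpec) -> Structure:
    """A large primary cuboid plus a small satellite cuboid on shared slices.

    The satellite sits ``separation`` mm away along x and appears on every
    primary slice within its own z extent, so removing it changes the
    per-slice region count — the fixture for topology-change detection.
    """
    if spec.kind != "multi_region":
        raise ParameterError(f"make_multi_region got kind {spec.kind!r}")
    sx, sy, sz = (
        spec.size if isinstance(spec.size, tuple) else (spec.size, spec.size, spec.size)
    )
    sat = spec.satellite_size
    if spec.separation <= sx / 2 + sat / 2:
        raise ParameterError("satellite overlaps the primary component")
    cx, cy, cz = spec.center
    primary = make_cuboid(replace(spec, kind="cuboid"))
    contours = list(primary.contours)
    scx = cx + spec.separation
    half = sat / 2
    sat_square = np.array(
        [[scx - half, cy - half], [scx + half, cy - half], [scx + half, cy + half], [scx - half, cy + half]]
    )
    for z in _slice_positions(cz, sz, spec.dz):
        if abs(z - cz) <= sat / 2 + 1e-9:
            contours.append(PlanarContour(sat_square, z))
    return Structure(name="multi_region", contours=contours)


def make_structure(spec: ShapeSpec) -> Structure:
    maker = {
        "cuboid": make_cuboid,
        "octahedron": make_octahedron,
        "multi_region": make_multi_region,
    }.get(spec.kind)
    if maker is None:
        raise ParameterError(f"unknown shape kind {spec.kind!r}")
    return maker(spec)


def snap_size_to_slice_lattice(size: float, dz: float) -> float:
    """Nearest positive multiple of 2*dz.

    Structures are centered at z = 0, so a height that is a multiple of
    2*dz keeps every slice on the shared lattice of dz multiples — which
    mask-based round trips (that snap contours onto grid planes) rely on.
    """
    return max(1, round(size / (2 * dz))) * 2 * dz


def make_dataset1(
    offset: tuple[float, float, float] = (5.0, 0.0, 0.0),
    dz: float = 2.5,
    cube_size: float = 50.0,
    octa_half_diagonal: float = 50.0,
    dense_spacing: float = 1.0,
) -> list[tuple[Structure, Structure]]:
    """The six analytic reference/test pairs (Objects A-F).

    A, B: sparse cuboids; C, D: dense cuboids; E: sparse octahedron;
    F: dense octahedron.  B and D are smaller than A and C (nominally 80%,
    snapped onto the slice lattice).  Each test member is a rigid
    translation of its reference by ``offset`` so every similarity measure
    has a nonzero, analytically checkable value.
    """
    small = snap_size_to_slice_lattice(0.8 * cube_size, dz)
    specs = {
        "Object A": ShapeSpec("cuboid", size=cube_size, sampling="sparse", dz=dz),
        "Object B": ShapeSpec("cuboid", size=small, sampling="sparse", dz=dz),
        "Object C": ShapeSpec(
            "cuboid", size=cube_size, sampling="dense", vertex_spacing=dense_spacing, dz=dz
        ),
        "Object D": ShapeSpec(
            "cuboid", size=small, sampling="dense", vertex_spacing=dense_spacing, dz=dz
        ),
        "Object E": ShapeSpec("octahedron", size=octa_half_diagonal, sampling="sparse", dz=dz),
        "Object F": ShapeSpec(
            "octahedron",
            size=octa_half_diagonal,
            sampling="dense",
            vertex_spacing=dense_spacing,
            dz=dz,
        ),
    }
    pairs = []
    for name, spec in specs.items():
        ref = make_structure(spec)
        ref.name = name
        test = ref.translated(*offset)
        pairs.append((ref, test))
    return pairs


# ---------------------------------------------------------------------------
# perturbation simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerturbationConfig:
    """One simulated re-export behaviour; a simulated "system" is an
    ordered list of these."""

    mode: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in PERTURBATION_MODES:
            raise ConfigError(
                f"unknown perturbation mode {self.mode!r}; valid: {PERTURBATION_MODES}"
            )

    # convenience constructors -------------------------------------------------
    @classmethod
    def truncate_precision(cls, decimal_places: int) -> "PerturbationConfig":
        return cls("truncate_precision", {"decimal_places": int(decimal_places)})

    @classmethod
    def resample_path(cls, target_spacing: float) -> "PerturbationConfig":
        return cls("resample_path", {"target_spacing": float(target_spacing)})

    @classmethod
    def mask_roundtrip_2d(cls, grid: ImageGrid) -> "PerturbationConfig":
        return cls("mask_roundtrip_2d", {"grid": grid})

    @classmethod
    def mask_roundtrip_3d(cls, grid: ImageGrid) -> "PerturbationConfig":
        return cls("mask_roundtrip_3d", {"grid": grid})

    @classmethod
    def drop_small_regions(cls, min_region_area: float) -> "PerturbationConfig":
        return cls("drop_small_regions", {"min_region_area": float(min_region_area)})

    @classmethod
    def subsample_vertices(cls, keep_every_k: int) -> "PerturbationConfig":
        return cls("subsample_vertices", {"keep_every_k": int(keep_every_k)})

    @classmethod
    def densify_vertices(cls, max_segment: float) -> "PerturbationConfig":
        return cls("densify_vertices", {"max_segment": float(max_segment)})

    def describe(self) -> dict:
        params = {
            k: (v.to_dict() if isinstance(v, ImageGrid) else v) for k, v in self.params.items()
        }
        return {"mode": self.mode, "params": params, "seed": self.seed}


def _apply_truncate(s: Structure, params: dict) -> Structure:
    dp = params["decimal_places"]
    contours = [
        PlanarContour(np.round(c.vertices, dp), round(c.z, dp), c.geometric_type)
        for c in s.contours
    ]
    return replace(s, contours=contours)


def _apply_resample(s: Structure, params: dict) -> Structure:
    spacing = params["target_spacing"]
    if spacing <= 0:
        raise ConfigError("target_spacing must be positive")
    contours = [
        PlanarContour(_geom.resample_closed_uniform(c.vertices, spacing), c.z, c.geometric_type)
        for c in s.contours
    ]
    return replace(s, contours=contours)


def _apply_subsample(s: Structure, params: dict) -> Structure:
    k = params["keep_every_k"]
    if k < 1:
        raise ConfigError("keep_every_k must be >= 1")
    contours = []
    for c in s.contours:
        v = c.vertices[::k]
        contours.append(PlanarContour(v if len(v) >= 3 else c.vertices, c.z, c.geometric_type))
    return replace(s, contours=contours)


def _apply_densify(s: Structure, params: dict) -> Structure:
    max_segment = params["max_segment"]
    if max_segment <= 0:
        raise ConfigError("max_segment must be positive")
    contours = []
    for c in s.contours:
        a, b = _geom.closed_segments(c.vertices)
        pts = []
        for pa, pb in zip(a, b):
            length = float(np.linalg.norm(pb - pa))
            k = max(1, int(math.ceil(length / max_segment - 1e-9)))
            t = np.arange(k) / k
            pts.append(pa[None, :] + t[:, None] * (pb - pa)[None, :])
        contours.append(PlanarContour(np.vstack(pts), c.z, c.geometric_type))
    return replace(s, contours=contours)


def _apply_drop_small(s: Structure, params: dict) -> Structure:
    min_area = params["min_region_area"]
    z_tol = 1e-6
    kept: list[PlanarContour] = []
    for group in group_by_slice(s, z_tol) if not s.is_empty else []:
        components = _geom.region_components(group.contours)
        for c in group.contours:
            if not components:
                continue
            p = Point(c.vertices[0])
            comp = min(components, key=lambda g: g.distance(p))
            if comp.area >= min_area:
                kept.append(c)
    return replace(s, contours=kept)


def _extract_slice_contours(
    mask: np.ndarray, grid: ImageGrid, z: float
) -> list[PlanarContour]:
    """0.5-level iso-contours of a boolean in-plane mask, in patient mm.

    The mask is zero-padded so every loop closes; linear interpolation
    between voxel centers gives sub-voxel boundary placement.
    """
    padded = np.pad(mask.astype(float), 1)
    contours = []
    for loop in measure.find_contours(padded, 0.5):
        if len(loop) > 1 and np.allclose(loop[0], loop[-1]):
            loop = loop[:-1]
        if len(loop) < 3:
            continue
        x = grid.origin[0] + (loop[:, 1] - 1) * grid.dx
        y = grid.origin[1] + (loop[:, 0] - 1) * grid.dy
        contours.append(PlanarContour(np.column_stack([x, y]), z))
    return contours


def rasterize_slice(contours: list[PlanarContour], grid: ImageGrid) -> np.ndarray:
    """(ny, nx) boolean mask of voxel centers inside the even-odd region.

    Voxel centers exactly on an edge count as outside (strict interior)."""
    X, Y = np.meshgrid(grid.x_centers(), grid.y_centers())
    return _geom.points_in_even_odd(X, Y, contours)


def _ensure_inplane_cover(grid: ImageGrid, s: Structure, pad: int = 2) -> ImageGrid:
    """Expand the grid in-plane (keeping voxel alignment) to cover ``s``."""
    if s.is_empty:
        return grid
    smin, smax = s.bounds()
    ox, oy, oz = grid.origin
    nx, ny, nz = grid.shape
    lo_x = min(0, int(math.floor((smin[0] - ox) / grid.dx)) - pad)
    lo_y = min(0, int(math.floor((smin[1] - oy) / grid.dy)) - pad)
    hi_x = max(nx - 1, int(math.ceil((smax[0] - ox) / grid.dx)) + pad)
    hi_y = max(ny - 1, int(math.ceil((smax[1] - oy) / grid.dy)) + pad)
    if (lo_x, lo_y, hi_x, hi_y) == (0, 0, nx - 1, ny - 1):
        return grid
    return ImageGrid(
        grid.dx,
        grid.dy,
        grid.dz,
        (ox + lo_x * grid.dx, oy + lo_y * grid.dy, oz),
        (hi_x - lo_x + 1, hi_y - lo_y + 1, nz),
    )


def _apply_mask_2d(s: Structure, params: dict) -> Structure:
    grid = params.get("grid")
    if grid is None:
        raise ConfigError("mask_roundtrip_2d requires a grid")
    grid = _ensure_inplane_cover(grid, s)
    contours: list[PlanarContour] = []
    for group in group_by_slice(s, 1e-6) if not s.is_empty else []:
        mask = rasterize_slice(group.contours, grid)
        contours.extend(_extract_slice_contours(mask, grid, group.z))
    return replace(s, contours=contours)


def _apply_mask_3d(s: Structure, params: dict) -> Structure:
    grid = params.get("grid")
    if grid is None:
        raise ConfigError("mask_roundtrip_3d requires a grid")
    grid = _ensure_inplane_cover(grid, s)
    planes = grid.z_planes()
    volume = np.zeros((grid.shape[2], grid.shape[1], grid.shape[0]), dtype=bool)
    for group in group_by_slice(s, 1e-6) if not s.is_empty else []:
        iz = int(round((group.z - grid.origin[2]) / grid.dz))
        if not 0 <= iz < len(planes) or abs(planes[iz] - group.z) > grid.dz / 2:
            continue
        volume[iz] |= rasterize_slice(group.contours, grid)
    # volumetric smoothing: one binary closing at 1-voxel radius
    struct3 = ndimage.generate_binary_structure(3, 1)
    closed = ndimage.binary_closing(np.pad(volume, 1), structure=struct3)[1:-1, 1:-1, 1:-1]
    contours: list[PlanarContour] = []
    for iz in range(closed.shape[0]):
        if closed[iz].any():
            contours.extend(_extract_slice_contours(closed[iz], grid, float(planes[iz])))
    return replace(s, contours=contours)


_APPLIERS: dict[str, Callable[[Structure, dict], Structure]] = {
    "truncate_precision": _apply_truncate,
    "resample_path": _apply_resample,
    "mask_roundtrip_2d": _apply_mask_2d,
    "mask_roundtrip_3d": _apply_mask_3d,
    "drop_small_regions": _apply_drop_small,
    "subsample_vertices": _apply_subsample,
    "densify_vertices": _apply_densify,
}


def perturb(s: Structure, configs: list[PerturbationConfig]) -> Structure:
    """Apply a sequence of re-export behaviours in order.

    An empty list is the identity.  All modes are deterministic given the
    config (bit-reproducible)."""
    out = s
    for cfg in configs:
        applier = _APPLIERS.get(cfg.mode)
        if applier is None:
            raise ConfigError(f"unknown perturbation mode {cfg.mode!r}")
        out = applier(out, cfg.params)
    return out


def preset_systems(grid: ImageGrid) -> dict[str, list[PerturbationConfig]]:
    """Named perturbation sequences mirroring the empirically observed
    behaviour classes: vertex-preserving, minor movement, mask-based with
    fast convergence, and mask-based with heavy tails."""
    return {
        "preserve": [],
        "truncate6dp": [PerturbationConfig.truncate_precision(6)],
        "truncate2dp": [PerturbationConfig.truncate_precision(2)],
        "resample_fine": [PerturbationConfig.resample_path(0.25)],
        "mask2d": [PerturbationConfig.mask_roundtrip_2d(grid)],
        "mask3d": [PerturbationConfig.mask_roundtrip_3d(grid)],
        "drop_small": [PerturbationConfig.drop_small_regions(10.0)],
    }


def random_configs(
    n: int, rng: np.random.Generator, grid: ImageGrid
) -> list[list[PerturbationConfig]]:
    """``n`` randomly parameterized single-mode perturbation sequences."""
    out = []
    for _ in range(n):
        mode = rng.choice(PERTURBATION_MODES)
        if mode == "truncate_precision":
            cfg = PerturbationConfig.truncate_precision(int(rng.integers(1, 7)))
        elif mode == "resample_path":
            cfg = PerturbationConfig.resample_path(float(rng.uniform(0.2, 3.0)))
        elif mode == "mask_roundtrip_2d":
            cfg = PerturbationConfig.mask_roundtrip_2d(grid)
        elif mode == "mask_roundtrip_3d":
            cfg = PerturbationConfig.mask_roundtrip_3d(grid)
        elif mode == "drop_small_regions":
            cfg = PerturbationConfig.drop_small_regions(float(rng.uniform(1.0, 50.0)))
        elif mode == "subsample_vertices":
            cfg = PerturbationConfig.subsample_vertices(int(rng.integers(1, 5)))
        else:
            cfg = PerturbationConfig.densify_vertices(float(rng.uniform(0.2, 2.0)))
        out.append([cfg])
    return out
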