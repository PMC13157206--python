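import numpy as np
import pytest

from rtssqc.model import ImageGrid, PlanarContour, Structure
from rtssqc.synthetic import ShapeSpec, make_cuboid, make_multi_region, make_octahedron


def square_contour(side: float = 1.0, z: float = 0.0, center=(0.0, 0.0)) -> PlanarContour:
    cx, cy = center
    h = side / 2.0
    return PlanarContour(
        np.array([[cx - h, cy - h], [cx + h, cy - h], [cx + h, cy + h], [cx - h, cy + h]]),
        z,
    )


@pytest.fixture(scope="session")
def unit_square() -> PlanarContour:
    return PlanarContour(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]), 0.0)


@pytest.fixture(scope="session")
def sparse_cube_50() -> Structure:
    return make_cuboid(ShapeSpec("cuboid", size=50.0, sampling="sparse", dz=2.5))


@pytest.fixture(scope="session")
def dense_cube_50() -> Structure:
    return make_cuboid(
        ShapeSpec("cuboid", size=50.0, sampling="dense", vertex_spacing=1.0, dz=2.5)
    )


@pytest.fixture(scope="session")
def dense_cube_20() -> Structure:
    return make_cuboid(
        ShapeSpec("cuboid", size=20.0, sampling="dense", vertex_spacing=1.0, dz=2.5)
    )


@pytest.fixture(scope="session")
def octa_dense_20() -> Structure:
    return make_octahedron(
        ShapeSpec("octahedron", size=20.0, sampling="dense", vertex_spacing=1.0, dz=2.5)
    )


@pytest.fixture(scope="session")
def multi_region_default() -> Structure:
    return make_multi_region(ShapeSpec("multi_region", size=20.0, separation=30.0, dz=2.5))


@pytest.fixture()
def grid_1mm(sparse_cube_50) -> ImageGrid:
    return ImageGrid.covering([sparse_cube_50, sparse_cube_50.translated(5.0)], 1.0, 1.0, 2.5)
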