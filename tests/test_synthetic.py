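import numpy as np
import pytest

import oracle
from rtssqc.displacement import displacement_summary
from rtssqc.errors import ConfigError, ParameterError
from rtssqc.model import ImageGrid
from rtssqc.synthetic import (
    PerturbationConfig,
    ShapeSpec,
    make_cuboid,
    make_dataset1,
    make_multi_region,
    make_octahedron,
    make_structure,
    perturb,
    random_configs,
)
from rtssqc.similarity_polygon import vdsc


class TestCuboid:
    def test_sparse_cube_slices_and_vertices(self, sparse_cube_50):
        # end-slice convention: floor(50 / 2.5) + 1 slices, both extremes present
        assert sparse_cube_50.n_contours == 21
        assert all(c.n_vertices == 4 for c in sparse_cube_50.contours)
        zs = sparse_cube_50.z_values()
        assert zs[0] == -25.0 and zs[-1] == 25.0

    def test_dense_vertex_count_from_perimeter(self, dense_cube_50):
        # perimeter / spacing oracle: 4 * 50 / 1
        assert all(c.n_vertices == 200 for c in dense_cube_50.contours)

    def test_slice_area_analytic(self, dense_cube_50, sparse_cube_50):
        for s in (dense_cube_50, sparse_cube_50):
            for c in s.contours:
                assert c.area == pytest.approx(2500.0)

    def test_corners_always_included_in_dense(self, dense_cube_50):
        verts = {tuple(v) for v in dense_cube_50.contours[0].vertices}
        for corner in [(-25, -25), (25, -25), (25, 25), (-25, 25)]:
            assert corner in verts

    def test_spacing_larger_than_side_rejected(self):
        with pytest.raises(ParameterError):
            make_cuboid(ShapeSpec("cuboid", size=10.0, sampling="dense", vertex_spacing=11.0))

    def test_anisotropic_size(self):
        s = make_cuboid(ShapeSpec("cuboid", size=(10.0, 20.0, 5.0), dz=2.5))
        assert s.n_contours == 3
        assert s.contours[0].area == pytest.approx(200.0)


class TestOctahedron:
    def test_mid_slice_is_full_diamond(self):
        s = make_octahedron(ShapeSpec("octahedron", size=20.0, dz=2.5))
        mid = [c for c in s.contours if c.z == 0.0][0]
        verts = {tuple(v) for v in mid.vertices}
        assert verts == {(20.0, 0.0), (0.0, 20.0), (-20.0, 0.0), (0.0, -20.0)}

    def test_apex_slices_omitted(self):
        s = make_octahedron(ShapeSpec("octahedron", size=20.0, dz=2.5))
        zs = s.z_values()
        # slices at |z| = 20 would be points: dropped
        assert zs[0] == -17.5 and zs[-1] == 17.5

    def test_half_width_linear(self):
        a = 20.0
        s = make_octahedron(ShapeSpec("octahedron", size=a, dz=2.5))
        for c in s.contours:
            w = c.vertices[:, 0].max()
            assert w == pytest.approx(a - abs(c.z))


class TestDataset1:
    def test_six_pairs(self):
        assert len(make_dataset1()) == 6

    def test_taxonomy(self):
        pairs = make_dataset1()
        names = [ref.name for ref, _ in pairs]
        assert names == [f"Object {x}" for x in "ABCDEF"]
        sparse = {"Object A", "Object B", "Object E"}
        for ref, _ in pairs:
            per_slice = ref.contours[0].n_vertices
            if ref.name in sparse:
                assert per_slice == 4
            else:
                assert per_slice > 4

    def test_translation_preserves_vertex_counts(self):
        for ref, test in make_dataset1():
            assert ref.n_vertices == test.n_vertices
            assert ref.n_contours == test.n_contours

    def test_vdsc_closed_form(self):
        # 50 mm cubes offset 5 mm: 2 * (45*50*50) / (2 * 50^3) = 0.9
        ref, test = make_dataset1()[0]
        grid = ImageGrid.covering([ref, test], 1.0, 1.0, 2.5)
        assert vdsc(ref, test, grid) == pytest.approx(0.9, abs=1e-9)

    def test_vdsc_against_voxel_oracle(self):
        ref, test = make_dataset1()[0]
        grid = ImageGrid.covering([ref, test], 1.0, 1.0, 2.5)
        assert vdsc(ref, test, grid) == pytest.approx(
            oracle.vdsc_voxel_oracle(ref, test, step=0.5), abs=0.01
        )


class TestMultiRegion:
    def test_two_regions_on_shared_slices(self, multi_region_default):
        zs = [c.z for c in multi_region_default.contours]
        shared = [z for z in set(zs) if zs.count(z) == 2]
        assert shared  # satellite present on at least one slice
        for z in shared:
            assert abs(z) <= 3.0 + 1e-9  # satellite z extent

    def test_satellite_overlap_rejected(self):
        with pytest.raises(ParameterError, match="overlaps"):
            make_multi_region(ShapeSpec("multi_region", size=20.0, separation=10.0))

    def test_drop_small_regions_removes_satellite(self):
        s = make_multi_region(
            ShapeSpec("multi_region", size=20.0, separation=30.0, satellite_size=2.0)
        )
        out = perturb(s, [PerturbationConfig.drop_small_regions(10.0)])  # 4 mm^2 < 10 mm^2
        assert out.n_contours < s.n_contours
        assert all(c.area > 10.0 for c in out.contours)

    def test_drop_small_keeps_large_satellite(self, multi_region_default):
        out = perturb(multi_region_default, [PerturbationConfig.drop_small_regions(10.0)])
        assert out.n_contours == multi_region_default.n_contours

    def test_directional_max_matches_nearest_point_oracle(self, multi_region_default):
        grid = ImageGrid.covering([multi_region_default], 1.0, 1.0, 2.5)
        dropped = perturb(multi_region_default, [PerturbationConfig.drop_small_regions(40.0)])
        summ = displacement_summary(multi_region_default, dropped, grid)
        # oracle: nearest distance from satellite vertices to the primary boundary
        expected = max(
            oracle.nearest_boundary_distance(v, dropped.contours)
            for c in multi_region_default.contours
            for v in c.vertices
            if c.vertices[:, 0].max() > 15  # satellite contours only
        )
        assert summ.max_mm == pytest.approx(expected, abs=1e-9)
        reverse = displacement_summary(dropped, multi_region_default, grid)
        assert reverse.max_mm == pytest.approx(0.0, abs=1e-12)


class TestPerturb:
    def test_truncate_example(self):
        from rtssqc.model import PlanarContour, Structure

        s = Structure("t", [PlanarContour(np.array([[1.2345, 6.7891], [5, 0], [0, 5]]), 0.0)])
        out = perturb(s, [PerturbationConfig.truncate_precision(2)])
        np.testing.assert_allclose(out.contours[0].vertices[0], [1.23, 6.79])

    def test_empty_config_identity(self, dense_cube_20):
        out = perturb(dense_cube_20, [])
        assert out is dense_cube_20

    def test_mask_roundtrip_2d_bound(self, dense_cube_20):
        grid = ImageGrid.covering([dense_cube_20], 1.0, 1.0, 2.5)
        out = perturb(dense_cube_20, [PerturbationConfig.mask_roundtrip_2d(grid)])
        summ = displacement_summary(dense_cube_20, out, grid)
        assert summ.mean_mm < 0.5 * grid.in_plane_voxel_size

    def test_mask_roundtrip_3d_runs(self, dense_cube_20):
        grid = ImageGrid.covering([dense_cube_20], 1.0, 1.0, 2.5)
        out = perturb(dense_cube_20, [PerturbationConfig.mask_roundtrip_3d(grid)])
        assert out.n_contours >= dense_cube_20.n_contours - 1
        summ = displacement_summary(dense_cube_20, out, grid)
        assert summ.mean_mm < 1.0

    def test_subsample_and_densify_vertex_counts(self, dense_cube_20):
        sub = perturb(dense_cube_20, [PerturbationConfig.subsample_vertices(2)])
        assert all(c.n_vertices == 40 for c in sub.contours)
        dense = perturb(dense_cube_20, [PerturbationConfig.densify_vertices(0.5)])
        assert all(c.n_vertices == 160 for c in dense.contours)

    def test_drop_small_never_moves_surviving_vertices(self, multi_region_default):
        out = perturb(multi_region_default, [PerturbationConfig.drop_small_regions(40.0)])
        originals = {
            (c.z, tuple(v)) for c in multi_region_default.contours for v in c.vertices
        }
        for c in out.contours:
            for v in c.vertices:
                assert (c.z, tuple(v)) in originals

    def test_deterministic(self, dense_cube_20):
        grid = ImageGrid.covering([dense_cube_20], 1.0, 1.0, 2.5)
        cfgs = [PerturbationConfig.mask_roundtrip_3d(grid)]
        a = perturb(dense_cube_20, cfgs)
        b = perturb(dense_cube_20, cfgs)
        assert a.n_contours == b.n_contours
        for ca, cb in zip(a.contours, b.contours):
            np.testing.assert_array_equal(ca.vertices, cb.vertices)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError):
            PerturbationConfig("melt_contours", {})

    def test_mask_mode_requires_grid(self, dense_cube_20):
        with pytest.raises(ConfigError, match="grid"):
            perturb(dense_cube_20, [PerturbationConfig("mask_roundtrip_2d", {})])

    def test_random_configs_seeded(self, dense_cube_20):
        grid = ImageGrid.covering([dense_cube_20], 1.0, 1.0, 2.5)
        a = random_configs(20, np.random.default_rng(3), grid)
        b = random_configs(20, np.random.default_rng(3), grid)
        assert [c[0].describe() for c in a] == [c[0].describe() for c in b]


def test_make_structure_dispatch():
    assert make_structure(ShapeSpec("cuboid", size=10.0)).n_contours == 5
    with pytest.raises(ParameterError):
        make_structure(ShapeSpec("sphere", size=10.0))
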