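import numpy as np
import pytest

import oracle
from rtssqc.errors import AnalysisError
from rtssqc.model import ImageGrid, PlanarContour, Structure
from rtssqc.similarity_polygon import (
    ToleranceSpec,
    distances_2d,
    napl,
    napl_sweep,
    path_length,
    vdsc,
)
from rtssqc.synthetic import PerturbationConfig, ShapeSpec, make_cuboid, make_dataset1, perturb

from conftest import square_contour


class TestToleranceSpec:
    def test_defaults_resolved(self):
        grid = ImageGrid(0.8, 1.2, 2.5)
        spec = ToleranceSpec()
        assert spec.resolved_mm(grid) == pytest.approx(
            [0.008, 0.08, 0.4, 0.8, 1.6, 2.4]  # fractions of min(dx, dy)
        )

    def test_validation(self):
        with pytest.raises(ValueError):
            ToleranceSpec(())
        with pytest.raises(ValueError):
            ToleranceSpec((0.1, 0.1))
        with pytest.raises(ValueError):
            ToleranceSpec((-0.1, 0.5))


class TestPathLength:
    def test_unit_square(self, unit_square):
        assert path_length(unit_square) == pytest.approx(4.0)

    def test_50mm_square(self):
        assert path_length(square_contour(side=50.0)) == pytest.approx(200.0)

    def test_collinear_densification_invariant(self):
        base = square_contour(side=10.0)
        s = Structure("s", [base])
        densified = perturb(s, [PerturbationConfig.densify_vertices(0.7)])
        assert path_length(densified.contours[0]) == pytest.approx(path_length(base))


class TestNapl:
    def test_identity_zero_at_all_tolerances(self, dense_cube_20):
        for tol in (0.01, 0.1, 0.5, 1.0, 2.0, 3.0):
            assert napl(dense_cube_20, dense_cube_20, tol) == 0.0

    def test_disjoint_is_one(self):
        a = Structure("a", [square_contour(side=10.0)])
        b = Structure("b", [square_contour(side=10.0, center=(100.0, 0.0))])
        assert napl(a, b, 0.5) == 1.0

    def test_missing_slice_counts_fully_outside(self):
        a = Structure("a", [square_contour(z=0.0), square_contour(z=2.5)])
        b = Structure("b", [square_contour(z=0.0)])
        assert napl(a, b, 0.5) == pytest.approx(0.5)

    def test_offset_squares_against_dense_oracle(self):
        a = Structure("a", [square_contour(side=50.0)])
        b = Structure("b", [square_contour(side=50.0, center=(1.0, 0.0))])
        got = napl(a, b, 0.5)
        expected = oracle.napl_oracle(a, b, 0.5, n_per_slice=10_000)
        assert got == pytest.approx(expected, abs=0.02)
        # geometric sanity: the two x-faces (half the perimeter) are 1 mm off
        assert 0.4 < got < 0.6

    def test_anti_monotone_in_tolerance(self, dense_cube_20):
        grid = ImageGrid.covering([dense_cube_20], 1.0, 1.0, 2.5)
        noisy = perturb(dense_cube_20, [PerturbationConfig.mask_roundtrip_2d(grid)])
        values = napl_sweep(dense_cube_20, noisy, [0.01, 0.1, 0.5, 1.0, 2.0, 3.0])
        assert all(b <= a + 1e-12 for a, b in zip(values, values[1:]))
        assert all(0.0 <= v <= 1.0 for v in values)

    def test_sweep_matches_single(self, dense_cube_20):
        moved = dense_cube_20.translated(0.7)
        sweep = napl_sweep(dense_cube_20, moved, [0.25, 0.5, 1.0], max_segment=0.05)
        singles = [napl(dense_cube_20, moved, t, max_segment=0.05) for t in (0.25, 0.5, 1.0)]
        assert sweep == pytest.approx(singles)

    def test_empty_reference_rejected(self, dense_cube_20):
        with pytest.raises(AnalysisError):
            napl(Structure("empty", []), dense_cube_20, 0.5)


class TestVdsc:
    def test_identity(self, dense_cube_20):
        grid = ImageGrid.covering([dense_cube_20], 1.0, 1.0, 2.5)
        assert vdsc(dense_cube_20, dense_cube_20, grid) == pytest.approx(1.0)

    def test_disjoint(self):
        grid = ImageGrid(1.0, 1.0, 2.5)
        a = Structure("a", [square_contour(side=10.0)])
        b = Structure("b", [square_contour(side=10.0, center=(100.0, 0.0))])
        assert vdsc(a, b, grid) == 0.0

    def test_offset_cubes_closed_form(self):
        ref, test = make_dataset1()[0]
        grid = ImageGrid.covering([ref, test], 1.0, 1.0, 2.5)
        assert vdsc(ref, test, grid) == pytest.approx(0.9, abs=1e-9)

    def test_symmetric(self):
        ref, test = make_dataset1()[4]  # sparse octahedron pair
        grid = ImageGrid.covering([ref, test], 1.0, 1.0, 2.5)
        assert vdsc(ref, test, grid) == pytest.approx(vdsc(test, ref, grid))

    def test_translation_invariant(self):
        ref, test = make_dataset1()[0]
        grid = ImageGrid.covering([ref, test], 1.0, 1.0, 2.5)
        v1 = vdsc(ref, test, grid)
        v2 = vdsc(ref.translated(11.0, -4.0), test.translated(11.0, -4.0), grid)
        assert v1 == pytest.approx(v2)

    def test_hole_subtracts(self):
        outer = square_contour(side=20.0)
        hole = square_contour(side=10.0)
        annulus = Structure("ann", [outer, hole])
        full = Structure("full", [square_contour(side=20.0)])
        grid = ImageGrid(1.0, 1.0, 2.5)
        # V(ann) = 300, V(full) = 400, intersection = 300
        assert vdsc(annulus, full, grid) == pytest.approx(2 * 300 / (300 + 400))

    def test_both_empty_rejected(self):
        grid = ImageGrid(1.0, 1.0, 2.5)
        with pytest.raises(AnalysisError):
            vdsc(Structure("a", []), Structure("b", []), grid)


class TestDistances2D:
    def test_identity(self, dense_cube_20):
        d = distances_2d(dense_cube_20, dense_cube_20)
        assert d.hd2d_mm == 0.0
        assert d.hd95_2d_mm == 0.0
        assert d.hd50_2d_mm == 0.0
        assert d.msd2d_mm == 0.0

    def test_offset_squares_hd(self):
        a = Structure("a", [square_contour(side=50.0)])
        b = Structure("b", [square_contour(side=50.0, center=(2.0, 0.0))])
        d = distances_2d(a, b)
        assert d.hd2d_mm == pytest.approx(2.0, abs=0.1)  # corner-to-edge geometry

    def test_ordering_invariants(self):
        a = Structure("a", [square_contour(side=30.0)])
        b = Structure("b", [square_contour(side=30.0, center=(1.5, 0.7))])
        d = distances_2d(a, b)
        assert d.hd50_2d_mm <= d.hd95_2d_mm <= d.hd2d_mm
        assert d.msd2d_mm <= d.hd2d_mm

    def test_against_point_cloud_oracle(self):
        a = Structure("a", [square_contour(side=30.0)])
        b = Structure("b", [square_contour(side=30.0, center=(1.5, 0.7))])
        got = distances_2d(a, b)
        exp = oracle.distance_aggregates_oracle(a, b)
        for key in ("hd2d_mm", "hd95_2d_mm", "hd50_2d_mm", "msd2d_mm"):
            assert getattr(got, key) == pytest.approx(exp[key], abs=0.05)

    def test_pooled_mean_is_count_weighted(self):
        a = Structure("a", [square_contour(side=10.0)])
        b = Structure("b", [square_contour(side=10.0, center=(0.5, 0.0))])
        d = distances_2d(a, b)
        assert d.msd2d_mm == pytest.approx(float(d.pooled_mm.mean()))

    def test_unmatched_slice_warns_and_reports(self):
        a = Structure("a", [square_contour(z=0.0), square_contour(z=2.5)])
        b = Structure("b", [square_contour(z=0.0)])
        with pytest.warns(UserWarning, match="unmatched"):
            d = distances_2d(a, b)
        assert d.n_unmatched_ab > 0
        assert d.dir_max_ab_mm == np.inf
        assert np.isfinite(d.hd2d_mm)

    def test_both_empty_rejected(self):
        with pytest.raises(AnalysisError):
            distances_2d(Structure("a", []), Structure("b", []))


class TestOracleEquivalenceOnPairs:
    """Polygon measures vs independent brute-force oracles (synthetic pairs)."""

    @pytest.mark.parametrize("index", [0, 4])  # sparse cube pair, sparse octa pair
    def test_vdsc_oracle(self, index):
        ref, test = make_dataset1(cube_size=30.0, octa_half_diagonal=30.0)[index]
        grid = ImageGrid.covering([ref, test], 1.0, 1.0, 2.5)
        got = vdsc(ref, test, grid)
        exp = oracle.vdsc_voxel_oracle(ref, test, step=0.25)
        assert got == pytest.approx(exp, abs=0.02)

    def test_napl_oracle_on_pair(self):
        ref, test = make_dataset1(cube_size=30.0)[0]
        got = napl(ref, test, 1.0, z_tol=0.25)
        exp = oracle.napl_oracle(ref, test, 1.0, n_per_slice=4000)
        assert got == pytest.approx(exp, abs=0.02)
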