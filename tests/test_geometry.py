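import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ryrarray.errors import (
    DegenerateGeometryError,
    InsufficientDataError,
    InvalidInputError,
)
from ryrarray.geometry import (
    ShapeParams,
    Tetramer,
    TetramerArray,
    alpha_shape_area,
    convex_hull_area,
    coverage_fraction,
    nearest_neighbour_distances,
    pair_relation,
)

from oracles import alpha_area_oracle, nnd_oracle, shoelace_hull_area


def tet(tid, x, y, theta=0.0, **kw):
    return Tetramer(tid, x, y, theta, tomogram_id=kw.pop("tomogram_id", "t0"), **kw)


class TestTetramer:
    def test_orientation_reduced_modulo_90(self):
        assert tet("a", 0, 0, 95.0).theta == pytest.approx(5.0)
        assert tet("a", 0, 0, -10.0).theta == pytest.approx(80.0)

    def test_footprint_area_is_side_squared(self):
        assert tet("a", 0, 0).footprint_area == pytest.approx(729.0)

    def test_non_finite_coordinates_rejected(self):
        with pytest.raises(InvalidInputError):
            Tetramer("a", math.nan, 0.0)
        with pytest.raises(InvalidInputError):
            Tetramer("a", 0.0, math.inf)

    def test_corners_span_the_side(self):
        c = tet("a", 10, -5, 30.0).corners()
        for i in range(4):
            edge = c[(i + 1) % 4] - c[i]
            assert np.linalg.norm(edge) == pytest.approx(27.0)


class TestTetramerArray:
    def test_overlapping_footprints_rejected(self):
        with pytest.raises(InvalidInputError, match="overlap"):
            TetramerArray((tet("a", 0, 0), tet("b", 10, 0)))

    def test_mixed_tomograms_rejected(self):
        with pytest.raises(InvalidInputError):
            TetramerArray(
                (tet("a", 0, 0), Tetramer("b", 100, 0, tomogram_id="other"))
            )

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            TetramerArray(())


class TestPairRelation:
    @pytest.mark.parametrize(
        "b_pos, gap, overlap, distance",
        [
            ((28.0, 0.0), 1.0, 27.0, 28.0),  # abutting side-by-side
            ((28.0, 20.0), 1.0, 7.0, math.hypot(28, 20)),  # checkerboard step
            ((0.0, 60.0), 33.0, 27.0, 60.0),  # distant translation
        ],
    )
    def test_axis_aligned_examples(self, b_pos, gap, overlap, distance):
        rel = pair_relation(tet("a", 0, 0), tet("b", *b_pos))
        assert rel.parallel
        assert rel.gap == pytest.approx(gap)
        assert rel.overlap == pytest.approx(overlap)
        assert rel.centre_distance == pytest.approx(distance)

    def test_non_parallel_pair_has_no_gap(self):
        rel = pair_relation(tet("a", 0, 0, 0.0), tet("b", 40, 0, 30.0))
        assert not rel.parallel
        assert rel.gap is None and rel.overlap is None
        assert rel.delta_theta == pytest.approx(30.0)

    def test_angle_difference_wraps_modulo_90(self):
        rel = pair_relation(tet("a", 0, 0, 2.0), tet("b", 40, 0, 88.0))
        assert rel.delta_theta == pytest.approx(4.0)
        assert rel.parallel

    def test_symmetry_in_arguments(self, rng):
        for _ in range(200):
            a = tet("a", *rng.uniform(-50, 50, 2), rng.uniform(0, 90))
            b = tet("b", *rng.uniform(-50, 50, 2), rng.uniform(0, 90))
            r1 = pair_relation(a, b)
            r2 = pair_relation(b, a)
            assert r1.centre_distance == pytest.approx(r2.centre_distance)
            assert r1.delta_theta == pytest.approx(r2.delta_theta)
            assert r1.parallel == r2.parallel
            if r1.parallel:
                assert r1.gap == pytest.approx(r2.gap, abs=1e-9)
                assert r1.overlap == pytest.approx(r2.overlap, abs=1e-9)

    def test_gap_plus_side_equals_axis_separation(self, rng):
        """For axis-aligned squares separated along x, gap + side == |dx|."""
        for _ in range(1000):
            dx = rng.uniform(27.0, 200.0)
            dy = rng.uniform(-26.0, 26.0)
            rel = pair_relation(tet("a", 0, 0), tet("b", dx, dy))
            assert rel.gap + 27.0 == pytest.approx(dx, abs=1e-9)

    def test_mismatched_sides_rejected(self):
        with pytest.raises(InvalidInputError):
            pair_relation(tet("a", 0, 0), tet("b", 40, 0, side=20.0))


class TestNearestNeighbourDistances:
    def test_mutual_pair(self):
        arr = TetramerArray((tet("a", 0, 0), tet("b", 28, 0)))
        assert [d for _, d in nearest_neighbour_distances(arr)] == [28.0, 28.0]

    def test_three_on_a_line(self):
        arr = TetramerArray((tet("a", 0, 0), tet("b", 28, 0), tet("c", 62, 0)))
        assert [d for _, d in nearest_neighbour_distances(arr)] == [28.0, 28.0, 34.0]

    def test_matches_brute_force_oracle(self, rng):
        """Random non-overlapping squares agree exactly with the O(n²) oracle."""
        for n in (10, 50, 200):
            kept: list[np.ndarray] = []
            while len(kept) < n:
                p = rng.uniform(0, 3000, 2)
                # pairwise distance > side*sqrt(2) so footprints cannot overlap
                if all(np.linalg.norm(p - q) > 39.0 for q in kept):
                    kept.append(p)
            coords = np.array(kept)
            arr = TetramerArray(
                tuple(tet(f"t{i}", x, y) for i, (x, y) in enumerate(coords))
            )
            got = np.array([d for _, d in nearest_neighbour_distances(arr)])
            assert np.array_equal(got, nnd_oracle(coords))

    def test_single_tetramer_raises(self):
        with pytest.raises(InsufficientDataError):
            nearest_neighbour_distances(TetramerArray((tet("a", 0, 0),)))


class TestAlphaShapeArea:
    def test_square_in_convex_regime(self):
        _, area = alpha_shape_area(
            [(0, 0), (100, 0), (100, 100), (0, 100)], ShapeParams(100.0)
        )
        assert area == pytest.approx(10000.0)

    def test_single_tetramer_footprint(self):
        _, area = alpha_shape_area(tet("a", 0, 0).corners(), ShapeParams(50.0))
        assert area == pytest.approx(729.0)

    def test_large_alpha_equals_convex_hull(self, rng):
        for _ in range(20):
            pts = rng.uniform(0, 500, (rng.integers(5, 40), 2))
            _, area = alpha_shape_area(pts, ShapeParams(1e9))
            assert area == pytest.approx(shoelace_hull_area(pts), rel=1e-6)
            assert area == pytest.approx(convex_hull_area(pts), rel=1e-6)

    def test_concave_c_shape_matches_brute_force(self, rng):
        """A C-shaped point set is carved below its hull and matches the
        exhaustive empty-circumcircle oracle within 2%."""
        angles = np.linspace(0.25 * np.pi, 1.75 * np.pi, 14)
        pts = 80.0 * np.column_stack([np.cos(angles), np.sin(angles)])
        pts += rng.normal(0, 1.0, pts.shape)  # break cocircularity
        _, area = alpha_shape_area(pts, ShapeParams(50.0))
        assert area < shoelace_hull_area(pts)
        assert area == pytest.approx(alpha_area_oracle(pts, 50.0), rel=0.02)

    def test_area_never_exceeds_hull(self, rng):
        for _ in range(20):
            pts = rng.uniform(0, 300, (15, 2))
            _, area = alpha_shape_area(pts, ShapeParams(40.0))
            assert area <= shoelace_hull_area(pts) + 1e-9

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateGeometryError):
            alpha_shape_area([(0, 0), (1, 1)], ShapeParams(50.0))
        with pytest.raises(DegenerateGeometryError):
            alpha_shape_area([(0, 0), (10, 10), (20, 20), (30, 30)], ShapeParams(50.0))


class TestCoverageFraction:
    def test_single_tetramer_is_fully_covered(self):
        assert coverage_fraction(TetramerArray((tet("a", 0, 0),))) == 1.0

    def test_two_abutting_tetramers_cover_their_rectangle(self):
        arr = TetramerArray((tet("a", 0, 0), tet("b", 27, 0)))
        assert coverage_fraction(arr) == pytest.approx(1.0)

    def test_checkerboard_pair_matches_brute_force(self):
        arr = TetramerArray((tet("a", 0, 0), tet("b", 28, 20)))
        corners = np.vstack([t.corners() for t in arr])
        expected = 2 * 729.0 / alpha_area_oracle(corners, 50.0)
        assert coverage_fraction(arr) == pytest.approx(expected, rel=1e-6)
        assert coverage_fraction(arr) < 1.0


@given(
    dx=st.floats(27.5, 150.0),
    dy=st.floats(-26.0, 26.0),
    scale=st.floats(0.5, 3.0),
)
def test_pair_relation_scales_with_geometry(dx, dy, scale):
    """Scaling coordinates and side by one factor scales gap and overlap."""
    r1 = pair_relation(Tetramer("a", 0, 0), Tetramer("b", dx, dy))
    r2 = pair_relation(
        Tetramer("a", 0, 0, side=27.0 * scale),
        Tetramer("b", dx * scale, dy * scale, side=27.0 * scale),
    )
    assert r2.gap == pytest.approx(r1.gap * scale, rel=1e-9, abs=1e-9)
    assert r2.overlap == pytest.approx(r1.overlap * scale, rel=1e-9, abs=1e-9)
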