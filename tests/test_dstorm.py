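import numpy as np
import pytest

from ryrarray.dstorm import (
    Cluster,
    ClusterParams,
    Localization,
    PixelGrid,
    QCThresholds,
    analyze_localizations,
    cluster_areas,
    clusters_frame,
    estimate_tetramers,
    link_clusters,
    qc_filter,
    rasterize,
)
from ryrarray.errors import ConfigurationError, InvalidInputError
from oracles import linkage_components_oracle


def loc(x, y, z=0.0, sigma_xy=5.0, sigma_z=20.0, gof=0.95):
    return Localization(x, y, z, sigma_xy, sigma_z, gof)


class TestQCFilter:
    def test_close_high_quality_pair_kept(self):
        locs = [loc(0, 0), loc(20, 0)]
        assert qc_filter(locs) == locs

    def test_each_exclusion_rule_fires(self):
        locs = [
            loc(0, 0, sigma_xy=12.0),  # XY error too large
            loc(10, 0, gof=0.85),  # poor fit
            loc(200, 200),  # good but > 30 nm from everything
        ]
        assert qc_filter(locs) == []

    def test_sigma_z_and_slice_rules(self):
        locs = [loc(0, 0, sigma_z=50.0), loc(10, 0, z=100.0), loc(20, 0), loc(30, 0)]
        assert qc_filter(locs) == locs[2:]

    def test_neighbour_test_runs_after_quality_stage(self):
        """A blink whose only close neighbour fails the gof rule becomes
        isolated and is removed by the staged 30-nm test."""
        locs = [loc(0, 0), loc(20, 0, gof=0.5)]
        assert qc_filter(locs) == []

    def test_boundary_values_are_inclusive(self):
        locs = [loc(0, 0, sigma_xy=10.0, sigma_z=40.0, gof=0.9), loc(30, 0)]
        assert qc_filter(locs) == locs

    def test_infinite_thresholds_are_identity(self, rng):
        locs = [
            loc(*rng.uniform(0, 1000, 2), z=rng.uniform(-200, 200),
                sigma_xy=rng.uniform(0, 30), gof=rng.uniform(0, 1))
            for _ in range(50)
        ]
        thr = QCThresholds(
            max_sigma_xy=None, max_sigma_z=None, min_gof=None,
            max_nn=None, z_slice=None,
        )
        assert qc_filter(locs, thr) == locs

    def test_never_increases_count(self, rng):
        locs = [loc(*rng.uniform(0, 500, 2)) for _ in range(100)]
        assert len(qc_filter(locs)) <= len(locs)

    def test_empty_input_is_empty_output(self):
        assert qc_filter([]) == []


class TestRasterize:
    def test_single_isolated_blink_gives_empty_grid(self):
        grid = rasterize([loc(5, 5)])
        assert grid.lit == set()

    def test_two_blinks_in_one_pixel_stay_lit(self):
        grid = rasterize([loc(5, 5), loc(6, 6)])
        assert grid.lit == {(0, 0)}
        assert grid.counts[(0, 0)] == 2

    def test_diagonal_single_blink_pixels_support_each_other(self):
        grid = rasterize([loc(5, 5), loc(15, 15)])
        assert grid.lit == {(0, 0), (1, 1)}

    def test_pixels_are_half_open(self):
        grid = rasterize([loc(0, 0), loc(10, 0), loc(9.999, 0)])
        assert grid.lit == {(0, 0), (1, 0)}
        assert grid.counts[(0, 0)] == 2

    def test_origin_defaults_to_minimum(self):
        grid = rasterize([loc(103, 57), loc(111, 57)])
        assert grid.origin == (103.0, 57.0)
        assert grid.pixel_centre((0, 0)) == (108.0, 62.0)


class TestLinkClusters:
    def _block(self, x0, y0):
        return [loc(x0 + 10 * i + 5, y0 + 10 * j + 5) for i in range(3) for j in range(3)]

    def test_blocks_within_linkage_merge(self):
        # nearest pixel centres 40 nm apart -> one cluster
        grid = rasterize(self._block(0, 0) + self._block(60, 0))
        assert len(link_clusters(grid)) == 1

    def test_blocks_beyond_linkage_split(self):
        # nearest pixel centres 60 nm apart -> two clusters
        grid = rasterize(self._block(0, 0) + self._block(80, 0))
        assert len(link_clusters(grid)) == 2

    def test_matches_union_find_oracle(self, rng):
        for _ in range(10):
            pts = rng.uniform(0, 400, (rng.integers(20, 80), 2))
            locs = [loc(x, y) for x, y in pts] + [loc(x + 1, y + 1) for x, y in pts]
            grid = rasterize(locs)
            clusters = link_clusters(grid)
            pixels = sorted(grid.counts)
            centres = grid.centres(pixels)
            want = linkage_components_oracle(pixels, centres, 50.0)
            assert sorted(c.pixels for c in clusters) == sorted(want)

    def test_every_lit_pixel_in_exactly_one_cluster(self, rng):
        pts = rng.uniform(0, 300, (60, 2))
        grid = rasterize([loc(x, y) for x, y in pts for _ in (0, 1)])
        clusters = link_clusters(grid)
        union = set().union(*(c.pixels for c in clusters))
        assert union == grid.lit
        assert sum(c.n_pixels for c in clusters) == len(grid.lit)


class TestClusterAreas:
    def _grid_block(self, n):
        locs = [
            loc(10 * i + 5, 10 * j + 5) for i in range(n) for j in range(n)
        ]
        grid = rasterize(locs)
        return grid, link_clusters(grid)

    def test_5x5_block_sits_on_the_filter_boundary_and_survives(self):
        grid, clusters = self._grid_block(5)
        kept = cluster_areas(clusters, grid)
        assert len(kept) == 1
        assert kept[0].area == pytest.approx(1600.0)

    def test_4x4_block_is_noise(self):
        grid, clusters = self._grid_block(4)
        assert cluster_areas(clusters, grid) == []

    def test_two_pixel_cluster_is_degenerate(self):
        grid = rasterize([loc(5, 5), loc(5, 6), loc(15, 5), loc(15, 6)])
        clusters = link_clusters(grid)
        assert cluster_areas(clusters, grid) == []

    def test_collinear_pixels_are_degenerate(self):
        locs = [loc(10 * i + 5, 5) for i in range(8) for _ in (0, 1)]
        grid = rasterize(locs)
        clusters = link_clusters(grid)
        assert cluster_areas(clusters, grid) == []


class TestEstimateTetramers:
    @pytest.mark.parametrize(
        "area, coverage, expected",
        [
            (12200.0, 0.495, 8),
            (729.0, 1.0, 1),
            (16000.0, 0.449, 10),
        ],
    )
    def test_worked_examples(self, area, coverage, expected):
        params = ClusterParams(coverage=coverage)
        assert estimate_tetramers(area, params) == expected

    def test_rounds_half_away_from_zero(self):
        params = ClusterParams(coverage=1.0)
        assert estimate_tetramers(729.0 * 2.5, params) == 3

    def test_unset_coverage_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            estimate_tetramers(10000.0, ClusterParams())

    def test_monotone_in_area_and_coverage(self, rng):
        areas = np.sort(rng.uniform(1600, 50000, 50))
        for cov_lo, cov_hi in [(0.3, 0.5), (0.449, 0.625)]:
            lo = [estimate_tetramers(a, ClusterParams(coverage=cov_lo)) for a in areas]
            hi = [estimate_tetramers(a, ClusterParams(coverage=cov_hi)) for a in areas]
            assert all(x <= y for x, y in zip(lo, lo[1:]))
            assert all(x <= y for x, y in zip(lo, hi))

    def test_median_count_commutes_with_median_area(self, rng):
        """With one group-level coverage scalar the estimator is a monotone
        transform, so the median count equals the count of the median area
        (up to rounding ties at the 0.5 boundary)."""
        params = ClusterParams(coverage=0.495)
        areas = rng.uniform(1600, 40000, 201)  # odd count: unique median
        counts = np.array([estimate_tetramers(a, params) for a in areas])
        med_count = float(np.median(counts))
        count_of_median = estimate_tetramers(float(np.median(areas)), params)
        assert abs(med_count - count_of_median) <= 1.0


class TestPipeline:
    def test_planted_clusters_recovered_end_to_end(self, rng):
        """Three well-separated blink clouds survive QC, rasterization,
        linkage and the noise filter as exactly three clusters with areas
        close to the generating footprints."""
        rects = [(0, 0, 250, 250), (700, 0, 950, 300), (0, 800, 300, 1050)]
        locs = []
        for x1, y1, x2, y2 in rects:
            n = 2000
            pts = rng.uniform((x1, y1), (x2, y2), (n, 2))
            noise = rng.normal(0, 5.0, (n, 2))
            locs += [loc(p[0] + e[0], p[1] + e[1]) for p, e in zip(pts, noise)]
        params = ClusterParams(coverage=0.5)
        clusters, _ = analyze_localizations(locs, params=params)
        assert len(clusters) == len(rects)
        true_areas = sorted((x2 - x1) * (y2 - y1) for x1, y1, x2, y2 in rects)
        got_areas = sorted(c.area for c in clusters)
        for got, want in zip(got_areas, true_areas):
            assert got == pytest.approx(want, rel=0.25)
        assert all(c.n_tetramers == round(c.area * 0.5 / 729.0) for c in clusters)

    def test_clusters_frame_columns(self):
        frame = clusters_frame(
            [Cluster(pixels=frozenset({(0, 0)}), area=2000.0, n_tetramers=2)]
        )
        assert list(frame.columns) == ["cluster_id", "area_nm2", "n_pixels", "n_tetramers"]


class TestValidation:
    def test_negative_uncertainty_rejected(self):
        with pytest.raises(InvalidInputError):
            Localization(0, 0, sigma_xy=-1.0)

    def test_gof_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            Localization(0, 0, gof=1.5)

    def test_bad_grid_rejected(self):
        with pytest.raises(InvalidInputError):
            PixelGrid(pixel_size=-10.0, origin=(0, 0), counts={})
        with pytest.raises(InvalidInputError):
            PixelGrid(pixel_size=10.0, origin=(0, 0), counts={(0, 0): 0})

    def test_bad_cluster_params_rejected(self):
        with pytest.raises(InvalidInputError):
            ClusterParams(coverage=1.5)
        with pytest.raises(InvalidInputError):
            ClusterParams(linkage=0.0)
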