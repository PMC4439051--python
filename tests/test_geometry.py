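"""Window, intensity and K-function estimation checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon

import oracle_utils
from spatcc import PointPattern, StudyWindow, default_s_grid, intensity, k_function, pairwise_distances
from spatcc.geometry import EmptyPatternError, isotropic_weight


class TestStudyWindow:
    def test_rejects_self_intersecting_polygon(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(ValueError):
            StudyWindow(bowtie)

    def test_rejects_zero_area(self):
        with pytest.raises(ValueError):
            StudyWindow(Polygon([(0, 0), (1, 0), (2, 0)]))

    def test_boundary_points_are_inside(self, unit_window):
        assert unit_window.contains(np.array([[0.0, 0.5], [1.0, 1.0]])).all()

    def test_geojson_wkt_round_trip(self, km_window):
        w2 = StudyWindow.from_geojson(km_window.to_geojson())
        w3 = StudyWindow.from_wkt(km_window.boundary.wkt)
        assert w2.area == pytest.approx(km_window.area)
        assert w3.area == pytest.approx(km_window.area)

    def test_pattern_outside_window_rejected(self, unit_window):
        with pytest.raises(ValueError):
            PointPattern([[2.0, 2.0]], unit_window)


class TestIntensity:
    @pytest.mark.parametrize(
        "coords, window_size, expected",
        [
            ([[1, 1], [2, 2]], 10.0, 0.02),
            (np.random.default_rng(0).uniform(0, 100, (100, 2)), 100.0, 0.01),
            ([[0.5, 0.5]], 1.0, 1.0),
        ],
    )
    def test_is_count_over_area(self, coords, window_size, expected):
        w = StudyWindow.rectangle(0, 0, window_size, window_size)
        assert intensity(PointPattern(coords, w)) == pytest.approx(expected)

    def test_empty_pattern_errors(self, unit_window):
        with pytest.raises(EmptyPatternError):
            intensity(PointPattern(np.empty((0, 2)), unit_window))


class TestPairwiseDistances:
    def test_known_geometry(self, km_window):
        d = pairwise_distances(PointPattern([[0, 0], [3, 4], [0, 0]], km_window))
        assert d[0, 1] == pytest.approx(5.0)
        assert d[0, 2] == 0.0
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_right_triangle(self, km_window):
        d = pairwise_distances(PointPattern([[0, 0], [1, 0], [0, 1]], km_window))
        assert d[1, 2] == pytest.approx(math.sqrt(2))

    def test_single_point_errors(self, km_window):
        with pytest.raises(EmptyPatternError):
            pairwise_distances(PointPattern([[1.0, 1.0]], km_window))


class TestKFunction:
    def test_two_point_textbook_value(self):
        # 2 points at distance 1 in a 10x10 window: mean neighbors 1, lambda 0.02
        w = StudyWindow.rectangle(0, 0, 10, 10)
        k = k_function(PointPattern([[4, 5], [5, 5]], w), np.array([2.0]), "none")
        assert k.k_values[0] == pytest.approx(50.0)
        assert k.lambda_hat == pytest.approx(0.02)

    def test_zero_below_minimum_interpoint_distance(self, km_window, rng):
        pts = rng.uniform(100, 900, (20, 2))
        dmin = pairwise_distances(PointPattern(pts, km_window))[
            ~np.eye(20, dtype=bool)
        ].min()
        k = k_function(PointPattern(pts, km_window), np.array([dmin * 0.5]), "isotropic")
        assert k.k_values[0] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_uncorrected_matches_double_loop_oracle(self, seed, km_window):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 50)
        pts = rng.uniform(0, 1000, (n, 2))
        s_grid = np.array([50.0, 200.0, 500.0, 1000.0])
        got = k_function(PointPattern(pts, km_window), s_grid, "none").k_values
        want = oracle_utils.k_naive_brute(pts, km_window.area, s_grid)
        np.testing.assert_allclose(got, want, rtol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_isotropic_matches_halfplane_oracle_on_convex_windows(self, seed):
        poly = Polygon([(0, 0), (1200, 100), (1500, 900), (600, 1400), (-100, 700)])
        w = StudyWindow(poly)
        rng = np.random.default_rng(seed)
        pts = []
        while len(pts) < 25:
            p = rng.uniform(-100, 1500, 2)
            if w.contains(p[None, :])[0]:
                pts.append(p)
        pts = np.array(pts)
        s_grid = np.array([100.0, 400.0, 900.0])
        got = k_function(PointPattern(pts, w), s_grid, "isotropic").k_values
        want = oracle_utils.k_iso_brute_convex(pts, poly, s_grid)
        np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_isotropic_weight_on_nonconvex_window_matches_discretization(self):
        lshape = Polygon([(0, 0), (1000, 0), (1000, 400), (400, 400), (400, 1000), (0, 1000)])
        w = StudyWindow(lshape)
        for center, r in [((100, 100), 350.0), ((350, 900), 500.0), ((900, 200), 250.0)]:
            got = isotropic_weight(w, center, r)
            frac = oracle_utils.circle_fraction_discretized(lshape, *center, r)
            assert got == pytest.approx(1.0 / frac, rel=5e-3)

    def test_isotropic_weights_at_least_one_and_unit_deep_inside(self, km_window, rng):
        for _ in range(20):
            c = rng.uniform(0, 1000, 2)
            r = rng.uniform(1, 800)
            w = isotropic_weight(km_window, c, r)
            assert w >= 1.0 or w == 0.0
        # full circle inside the window -> no correction
        assert isotropic_weight(km_window, (500.0, 500.0), 499.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("correction", ["none", "isotropic"])
    def test_rigid_motion_invariance(self, correction, rng):
        pts = rng.uniform(200, 800, (15, 2))
        w = StudyWindow.rectangle(0, 0, 1000, 1000)
        s_grid = np.array([100.0, 300.0, 700.0])
        base = k_function(PointPattern(pts, w), s_grid, correction).k_values
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([5000.0, -2000.0])
        pts2 = pts @ R.T + shift
        ring = np.asarray(w.boundary.exterior.coords) @ R.T + shift
        w2 = StudyWindow(Polygon(ring))
        moved = k_function(PointPattern(pts2, w2), s_grid, correction).k_values
        np.testing.assert_allclose(moved, base, rtol=1e-9)

    def test_uncorrected_k_is_nondecreasing(self, km_window, rng):
        pts = rng.uniform(0, 1000, (40, 2))
        k = k_function(PointPattern(pts, km_window), default_s_grid(1500.0), "none")
        assert np.all(np.diff(k.k_values) >= 0)

    def test_duplicate_coordinates_count_as_neighbors(self, km_window):
        pts = np.array([[500.0, 500.0], [500.0, 500.0], [900.0, 900.0]])
        k = k_function(PointPattern(pts, km_window), np.array([1.0]), "isotropic")
        # the coincident pair is a neighbor at every s > 0 (both orders)
        assert k.k_values[0] == pytest.approx(1e6 * 2 / 9)

    def test_invalid_grid_rejected(self, km_window, small_dataset):
        pat = PointPattern(small_dataset.coords, km_window)
        for bad in ([0.0, 1.0], [5.0, 5.0], [-1.0]):
            with pytest.raises(ValueError):
                k_function(pat, np.array(bad))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1000, allow_nan=False), st.floats(0, 1000, allow_nan=False)
            ),
            min_size=2,
            max_size=12,
        )
    )
    def test_uncorrected_equals_oracle_property(self, coords):
        w = StudyWindow.rectangle(0, 0, 1000, 1000)
        pts = np.asarray(coords)
        s_grid = np.array([10.0, 250.0, 1500.0])
        got = k_function(PointPattern(pts, w), s_grid, "none").k_values
        want = oracle_utils.k_naive_brute(pts, w.area, s_grid)
        np.testing.assert_allclose(got, want, rtol=1e-12)
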