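"""Bernoulli scan statistic: kernel, window enumeration, full scan."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracle_utils
from conftest import random_case_control
from spatcc import (
    CaseControlPattern,
    StudyWindow,
    enumerate_windows,
    expected_cases,
    log_lr_kernel,
    scan,
)


class TestKernel:
    def test_equal_risk_is_not_a_candidate(self):
        # 1/2 inside vs 2/4 outside sits exactly on the indicator boundary
        assert log_lr_kernel(1, 2, 2, 4) == -math.inf

    def test_zero_cases_inside_never_candidate(self):
        assert log_lr_kernel(0, 10, 5, 90) == -math.inf

    def test_all_cases_inside_window_value(self):
        # n_in=5, N_in=5, 633 cases among 4461 at-risk outside
        got = log_lr_kernel(5, 5, 633, 4461)
        want = 5 * math.log(1.0) + 633 * math.log(633 / 4461)
        assert got == pytest.approx(want, rel=1e-14)

    def test_errors_on_bad_counts(self):
        with pytest.raises(ValueError):
            log_lr_kernel(1, 0, 1, 10)
        with pytest.raises(ValueError):
            log_lr_kernel(5, 4, 1, 10)
        with pytest.raises(ValueError):
            log_lr_kernel(-1, 4, 1, 10)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        N_in=st.integers(1, 50),
        M_out=st.integers(0, 200),
        data=st.data(),
    )
    @pytest.mark.parametrize("kernel", ["paper", "bernoulli"])
    def test_matches_independent_formula(self, kernel, N_in, M_out, data):
        n_in = data.draw(st.integers(0, N_in))
        n_out = data.draw(st.integers(0, M_out))
        got = log_lr_kernel(n_in, N_in, n_out, M_out, kernel=kernel)
        want = oracle_utils.kernel_brute(n_in, N_in, n_out, M_out, kernel == "bernoulli")
        if math.isinf(want):
            assert got == -math.inf
        else:
            assert got == pytest.approx(want, rel=1e-12)


class TestExpectedCases:
    def test_zero_population_inside(self):
        assert expected_cases(100, 0, 700) == 0.0

    def test_requires_positive_total(self):
        with pytest.raises(ValueError):
            expected_cases(100, 0, 0)

    def test_sums_to_total_cases_over_partition(self, rng):
        C, N_total = 638, 4466
        parts = rng.multinomial(N_total, [0.2, 0.5, 0.3])
        total = sum(expected_cases(C, int(p), N_total) for p in parts)
        assert total == pytest.approx(C)


class TestEnumerateWindows:
    def test_singleton_when_isolated(self, km_window):
        data = CaseControlPattern(
            np.array([[100.0, 100.0], [900.0, 900.0]]),
            np.array([True, False]),
            km_window,
        )
        wins = enumerate_windows(data, max_radius=150.0)
        assert len(wins) == 1
        center, radii = wins[0]
        assert center == 0 and list(radii) == [0.0]

    def test_collinear_points_forced_geometry(self, km_window):
        data = CaseControlPattern(
            np.array([[0.0, 0.0], [100.0, 0.0], [200.0, 0.0]]),
            np.array([True, False, False]),
            km_window,
        )
        (center, radii), = enumerate_windows(data, max_radius=150.0)
        assert center == 0
        assert list(radii) == [0.0, 100.0]  # inside-sets {0} and {0,1}

    @pytest.mark.parametrize("seed", range(5))
    def test_inside_sets_match_exhaustive_oracle(self, seed, km_window):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 20))
        data = random_case_control(rng, max(1, n // 4), n - max(1, n // 4), km_window)
        want = oracle_utils.window_sets_brute(data.coords, data.is_case, 400.0)
        d = np.linalg.norm(
            data.coords[None, :, :] - data.coords[:, None, :], axis=-1
        )
        for center, radii in enumerate_windows(data, 400.0):
            got = {frozenset(np.flatnonzero(d[center] <= r).tolist()) for r in radii}
            assert got == want[center]


class TestScan:
    def test_fixed_seed_reproducible(self, km_window, rng):
        data = random_case_control(rng, 8, 40, km_window)
        a = scan(data, max_radius=500.0, n_replications=99, seed=42)
        b = scan(data, max_radius=500.0, n_replications=99, seed=42)
        assert a.primary.log_lr == b.primary.log_lr
        assert a.primary.p_value == b.primary.p_value
        assert a.primary.center == b.primary.center

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("kernel", ["paper", "bernoulli"])
    def test_primary_log_lr_matches_exhaustive_maximum(self, seed, kernel, km_window):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(10, 50))
        n_cases = max(2, n // 7)
        data = random_case_control(rng, n_cases, n - n_cases, km_window)
        res = scan(data, max_radius=600.0, n_replications=19, seed=0, kernel=kernel)
        want = oracle_utils.max_loglr_brute(
            data.coords, data.is_case, 600.0, full=(kernel == "bernoulli")
        )
        assert res.primary.log_lr == pytest.approx(want, rel=1e-12)

    def test_p_value_at_least_reciprocal(self, km_window, rng):
        data = random_case_control(rng, 5, 30, km_window)
        res = scan(data, max_radius=800.0, n_replications=39, seed=1)
        assert res.primary.p_value >= 1 / 40
        assert res.primary.p_value <= 1.0

    def test_cluster_count_invariants(self, km_window, rng):
        data = random_case_control(rng, 10, 60, km_window)
        res = scan(data, max_radius=700.0, n_replications=19, seed=2)
        for c in res.ranked:
            assert c.n_inside + c.n_outside == res.total_cases
            assert c.atrisk_inside + c.atrisk_outside == res.total_atrisk
            assert c.n_inside <= c.atrisk_inside
            # candidate indicator: risk inside strictly exceeds risk outside
            assert c.n_inside * c.atrisk_outside > c.n_outside * c.atrisk_inside
            assert c.expected_cases == pytest.approx(
                res.total_cases * c.atrisk_inside / res.total_atrisk
            )

    def test_reported_clusters_do_not_overlap(self, km_window, rng):
        data = random_case_control(rng, 12, 50, km_window)
        res = scan(data, max_radius=900.0, n_replications=19, seed=3)
        seen = set()
        for c in res.ranked:
            members = set(c.member_indices.tolist())
            assert not (members & seen)
            seen |= members

    def test_no_candidate_yields_empty_ranking(self, km_window):
        # case and control co-located: the only window holds both, equal risk
        data = CaseControlPattern(
            np.array([[500.0, 500.0], [500.0, 500.0]]),
            np.array([True, False]),
            km_window,
        )
        res = scan(data, max_radius=100.0, n_replications=19, seed=0)
        assert res.ranked == [] and res.primary is None

    def test_needs_both_groups(self, km_window):
        data = CaseControlPattern(
            np.array([[1.0, 1.0], [2.0, 2.0]]), np.array([True, True]), km_window
        )
        with pytest.raises(ValueError):
            scan(data, n_replications=19)

    def test_tie_broken_toward_smaller_radius(self, km_window):
        # two identical case pairs far apart: equal best windows; the reported
        # primary must be one of them at the pair radius, lowest center index
        coords = np.array(
            [[100.0, 100.0], [110.0, 100.0], [800.0, 800.0], [810.0, 800.0],
             [450.0, 450.0], [460.0, 470.0]]
        )
        is_case = np.array([True, True, True, True, False, False])
        data = CaseControlPattern(coords, is_case, km_window)
        res = scan(data, max_radius=300.0, n_replications=19, seed=0)
        assert res.primary.center_index == 0
        assert res.primary.radius == pytest.approx(10.0)
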