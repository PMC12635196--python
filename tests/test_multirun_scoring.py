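import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossrun_dia.alignment import SynchronizedPeptide
from crossrun_dia.multirun_scoring import (
    CrossRunProfile,
    average_profiles,
    find_elbow,
    multirun_score,
    pick_peaks,
    snr,
    weight_decay,
)


def _sync(stack):
    stack = np.asarray(stack, dtype=float)
    n_runs, G = stack.shape
    rt = np.arange(G, dtype=float) * 2.0
    return SynchronizedPeptide(
        "p", "r0", [f"r{i}" for i in range(n_runs)], rt,
        np.tile(rt, (n_runs, 1)), {"main_score": stack},
    )


class TestAverageProfiles:
    def test_identical_profiles_average_to_themselves(self):
        v = np.linspace(0, 1, 20)
        cross = average_profiles(_sync([v, v, v]))
        assert np.allclose(cross.averaged_main, v)

    def test_nan_runs_excluded_from_denominator(self):
        v = np.full(10, 0.6)
        nanrow = np.full(10, np.nan)
        cross = average_profiles(_sync([v, nanrow]))
        assert np.allclose(cross.averaged_main, 0.6)

    def test_all_nan_raises(self):
        with pytest.raises(ValueError, match="skipped"):
            average_profiles(_sync([np.full(5, np.nan)]))

    def test_peak_survives_averaging_with_flat_noise(self):
        rng = np.random.default_rng(0)
        peak = np.zeros(50)
        peak[25] = 1.0
        stack = [peak] + [rng.uniform(0, 0.2, 50) for _ in range(7)]
        cross = average_profiles(_sync(stack))
        assert np.argmax(cross.averaged_main) == 25


class TestSNR:
    def test_hand_arithmetic(self):
        v = np.full(100, 0.5)
        v[40:50] = 1.0
        rt = np.arange(100) * 2.0
        assert snr(v, rt, (80.0, 98.0)) == pytest.approx(2.0)

    def test_flat_profile_is_one(self):
        v = np.full(50, 0.3)
        assert snr(v, np.arange(50) * 2.0, (20.0, 40.0)) == pytest.approx(1.0)

    def test_zero_outside_is_inf(self):
        v = np.zeros(50)
        v[10:15] = 1.0
        assert snr(v, np.arange(50) * 2.0, (20.0, 28.0)) == np.inf

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            snr(np.ones(10), np.arange(10) * 2.0, (100.0, 110.0))


class TestPickPeaks:
    def _profile(self, v):
        v = np.asarray(v, dtype=float)
        return CrossRunProfile("p", np.arange(len(v)) * 2.0, v, np.ones(len(v), dtype=int))

    def test_single_clean_peak(self):
        v = np.exp(-0.5 * ((np.arange(100) - 50) / 4.0) ** 2)
        cands = pick_peaks(self._profile(v), min_separation=10.0)
        assert len(cands) == 1
        assert cands[0].apex_rt == 100.0

    def test_twelve_peaks_top_ten_returned(self):
        v = np.zeros(1000)
        heights = 0.3 + 0.05 * np.arange(12)
        centers = 40 + 80 * np.arange(12)
        for c, h in zip(centers, heights):
            v[c - 3 : c + 4] = h * np.array([0.3, 0.6, 0.9, 1.0, 0.9, 0.6, 0.3])
        cands = pick_peaks(self._profile(v), top_n=10, min_separation=20.0)
        assert len(cands) == 10
        kept_heights = sorted(c.apex_score for c in cands)
        assert kept_heights == sorted(heights[2:])  # the 10 highest

    def test_equal_maxima_lower_rt_ranked_first(self):
        v = np.zeros(100)
        v[[20, 60]] = 0.8
        cands = pick_peaks(self._profile(v), min_separation=10.0)
        assert cands[0].apex_rt == 40.0
        assert cands[0].rank == 1

    def test_min_separation_suppresses_shoulders(self):
        v = np.zeros(100)
        v[50] = 1.0
        v[53] = 0.9
        cands = pick_peaks(self._profile(v), min_separation=20.0)
        assert len(cands) == 1

    def test_boundaries_contain_apex(self):
        v = np.exp(-0.5 * ((np.arange(200) - 90) / 6.0) ** 2)
        c = pick_peaks(self._profile(v), min_separation=10.0)[0]
        assert c.left_rt <= c.apex_rt <= c.right_rt

    def test_flat_profile_no_candidates(self):
        assert pick_peaks(self._profile(np.zeros(50))) == []


class TestWeightDecay:
    def test_endpoints_exact(self):
        for k in (0.0, 1.0, 5.0, 50.0, 200.0):
            assert weight_decay(0.0, k) == 0.0
            assert weight_decay(1.0, k) == 1.0

    def test_half_at_k50_matches_closed_form(self):
        assert weight_decay(0.5, 50.0) == pytest.approx((50**0.5 - 1) / 49, abs=1e-12)

    def test_k_zero_and_k_one_are_identity(self):
        w = np.linspace(0, 1, 11)
        assert np.allclose(weight_decay(w, 0.0), w)
        assert np.allclose(weight_decay(w, 1.0), w)
        assert np.max(np.abs(weight_decay(w, 1.0 + 1e-8) - w)) < 1e-6

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(0.001, 0.999), st.floats(1.5, 300.0))
    def test_strictly_increasing_convex_and_below_identity(self, w, k):
        eps = 1e-4
        lo, hi = max(w - eps, 0.0), min(w + eps, 1.0)
        phi_lo, phi, phi_hi = weight_decay(lo, k), weight_decay(w, k), weight_decay(hi, k)
        assert phi_lo < phi < phi_hi  # strictly increasing
        assert phi <= w + 1e-12  # below identity for k > 1
        mid = weight_decay((lo + hi) / 2, k)
        assert mid <= (phi_lo + phi_hi) / 2 + 1e-12  # convex

    def test_weight_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            weight_decay(1.2, 50.0)


class TestMultirunScore:
    def test_identical_runs_weights_one_is_identity(self):
        s = np.full(5, 0.7)
        assert multirun_score(s, np.ones(5), 50.0, 0) == pytest.approx(0.7)

    def test_zero_weight_run_is_ignored(self):
        assert multirun_score(np.array([0.9, 0.1]), np.array([1.0, 0.0]), 50.0, 0) == pytest.approx(0.9)

    def test_hand_arithmetic_two_runs(self):
        phi = (50**0.5 - 1) / 49
        expected = (0.9 + phi * 0.1) / (1 + phi)
        got = multirun_score(np.array([0.9, 0.1]), np.array([1.0, 0.5]), 50.0, 0)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            s = rng.uniform(0, 1, 6)
            w = rng.uniform(0, 1, 6)
            w[0] = 1.0
            v = multirun_score(s, w, 50.0, 0)
            assert s.min() - 1e-12 <= v <= s.max() + 1e-12

    def test_nan_scores_skipped(self):
        s = np.array([0.8, np.nan, 0.4])
        v = multirun_score(s, np.array([1.0, 1.0, 1.0]), 0.0, 0)
        assert v == pytest.approx(0.6)

    def test_increasing_k_suppresses_low_weight_runs(self):
        s = np.array([0.2, 0.9])
        w = np.array([1.0, 0.5])
        scores = [multirun_score(s, w, k, 0) for k in (0.0, 10.0, 50.0, 200.0)]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_all_zero_weights_falls_back_to_target(self):
        with pytest.warns(UserWarning, match="falling back"):
            v = multirun_score(np.array([np.nan, 0.5]), np.array([0.0, 0.0]), 50.0, 1)
        assert v == 0.5


class TestFindElbow:
    def test_reference_curve_elbow(self):
        k = [0, 10, 25, 50, 100, 200]
        counts = [100, 60, 40, 38, 37, 37]
        assert find_elbow(k, counts) in (25.0, 50.0)

    def test_strictly_linear_decline_returns_smallest_k(self):
        with pytest.warns(UserWarning, match="linear|flat"):
            k = find_elbow([0, 10, 20, 30, 40], [100, 90, 80, 70, 60], gaussian_sigma=0.01)
        assert k == 0.0

    def test_flat_curve_returns_smallest_k(self):
        with pytest.warns(UserWarning, match="flat"):
            assert find_elbow([0, 10, 20, 30], [50, 50, 50, 50]) == 0.0

    def test_deterministic(self):
        k = [0, 5, 10, 25, 50, 100, 200]
        c = [500, 300, 200, 150, 140, 138, 137]
        assert find_elbow(k, c) == find_elbow(k, c)
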