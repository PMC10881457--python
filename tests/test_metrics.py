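"""TOPA scoring, z-scores, histograms and mode/cluster counting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from striatal_chunking import (
    aggregate_over_seeds,
    count_modes,
    peak_zscore,
    topa,
    topa_global,
    topa_histogram,
    window_minima,
)
from striatal_chunking.metrics import count_clusters, score_trace


class TestTopa:
    def test_linearly_rising_trace_peaks_at_window_end(self):
        trace = np.arange(400.0)
        offsets, peaks = topa(trace, [(100.0, 300.0)], dt=1.0)
        assert offsets[0] == 199.0  # window length - dt
        assert peaks[0] == 299.0

    def test_spike_at_window_start_gives_zero_offset(self):
        trace = np.zeros(200)
        trace[50] = 5.0
        offsets, _ = topa(trace, [(50.0, 150.0)], dt=1.0)
        assert offsets[0] == 0.0

    def test_ties_break_to_earliest_sample(self):
        trace = np.zeros(100)
        trace[[20, 40]] = 3.0
        offsets, _ = topa(trace, [(0.0, 100.0)], dt=1.0)
        assert offsets[0] == 20.0

    def test_matches_brute_force_scan_on_two_bump_traces(self, rng):
        """Exhaustive max oracle over synthetic multi-bump traces."""
        t = np.arange(1000.0)
        trace = (
            np.exp(-0.5 * ((t - 230) / 20) ** 2)
            + 0.7 * np.exp(-0.5 * ((t - 610) / 35) ** 2)
            + 0.05 * rng.normal(size=1000)
        )
        windows = [(100.0, 400.0), (450.0, 750.0), (800.0, 1000.0)]
        offsets, peaks = topa(trace, windows, dt=1.0)
        for j, (a, b) in enumerate(windows):
            best_k, best_v = 0, -np.inf
            for k in range(int(a), int(b)):
                if trace[k] > best_v:
                    best_k, best_v = k - int(a), trace[k]
            assert offsets[j] == best_k and peaks[j] == best_v

    def test_window_outside_trace_raises(self):
        with pytest.raises(IndexError):
            topa(np.zeros(100), [(50.0, 150.0)], dt=1.0)

    def test_offsets_bounded_by_window_length(self, rng):
        trace = rng.normal(size=500)
        windows = [(0.0, 200.0), (250.0, 450.0)]
        offsets, _ = topa(trace, windows, dt=1.0)
        assert np.all(offsets >= 0) and np.all(offsets < 200.0)

    def test_global_peak_selects_tallest_window(self):
        trace = np.zeros(300)
        trace[40] = 1.0
        trace[220] = 2.0
        off, peak = topa_global(trace, [(0.0, 100.0), (200.0, 300.0)], dt=1.0)
        assert (off, peak) == (20.0, 2.0)

    def test_window_minima_mirror_maxima(self):
        trace = np.zeros(100)
        trace[30] = -4.0
        offs, mins = window_minima(trace, [(0.0, 100.0)], dt=1.0)
        assert offs[0] == 30.0 and mins[0] == -4.0


class TestPeakZscore:
    def test_peak_at_trace_mean_scores_zero(self, rng):
        trace = rng.normal(size=1000)
        assert peak_zscore(trace, trace.mean()) == pytest.approx(0.0, abs=1e-12)

    def test_standard_normal_trace_peak_two_scores_two(self, rng):
        trace = rng.standard_normal(200_000)
        assert peak_zscore(trace, 2.0) == pytest.approx(2.0, abs=0.02)

    def test_constant_trace_returns_flagged_null(self):
        assert peak_zscore(np.full(100, 1.5), 1.5) is None
        out = peak_zscore(np.full(100, 1.5), np.array([1.5, 2.0]))
        assert np.isnan(out).all()


class TestHistogramAndModes:
    def test_all_offsets_identical_one_mode(self):
        counts, _ = topa_histogram(np.full(50, 75.0), 200.0, bin_width=10.0)
        assert counts.sum() == 50
        assert count_modes(counts) == 1

    def test_four_separated_positions_four_modes(self):
        offsets = np.repeat([5.0, 55.0, 105.0, 155.0], 25)
        counts, _ = topa_histogram(offsets, 200.0, bin_width=10.0)
        assert count_modes(counts) == 4

    def test_histogram_total_equals_windows_scored(self, rng):
        offsets = rng.uniform(0, 200, size=333)
        counts, _ = topa_histogram(offsets, 200.0, bin_width=10.0)
        assert counts.sum() == 333

    def test_modes_match_exhaustive_neighbor_oracle(self, rng):
        """Random histograms: plateau-aware local-maximum scan oracle."""
        for _ in range(50):
            counts = rng.integers(0, 30, size=12)
            floor = 0.05 * counts.max() if counts.max() else 0
            c = np.where(counts < floor, 0, counts).astype(float)
            expected = 0
            i = 0
            while i < len(c):
                j = i
                while j + 1 < len(c) and c[j + 1] == c[i]:
                    j += 1
                if (
                    c[i] > 0
                    and (i == 0 or c[i - 1] < c[i])
                    and (j == len(c) - 1 or c[j + 1] < c[i])
                ):
                    expected += 1
                i = j + 1
            assert count_modes(counts) == expected

    def test_mode_count_invariant_under_rescaling(self, rng):
        counts = rng.integers(0, 100, size=20)
        assert count_modes(counts) == count_modes(counts * 7)
        assert count_modes(counts) == count_modes(counts * 0.01)

    def test_noise_floor_sensitivity_on_separated_clusters(self):
        """Well-separated clusters: the count is stable across floors."""
        offsets = np.r_[
            np.repeat([10.0, 60.0, 110.0, 160.0], 40),
            np.random.default_rng(0).uniform(0, 200, 8),  # sparse background
        ]
        counts, _ = topa_histogram(offsets, 200.0, bin_width=10.0)
        results = {f: count_modes(counts, noise_floor=f) for f in (0.03, 0.05, 0.1, 0.2)}
        assert results[0.05] == 4
        assert len(set(results.values())) == 1, f"floor sensitivity: {results}"

    def test_cluster_count_per_character_positions(self):
        """Clusters = character-duration bins holding non-negligible mass."""
        offsets = np.r_[np.repeat([20.0, 70.0, 120.0, 170.0], 30)]
        assert count_clusters(offsets, window_length=200.0, char_duration=50.0) == 4
        concentrated = np.r_[np.full(97, 180.0), [20.0, 70.0, 120.0]]
        assert count_clusters(concentrated, 200.0, 50.0) == 1


class TestAggregation:
    def test_single_seed_single_window_mean(self):
        assert aggregate_over_seeds([np.array([42.0])], "mean") == 42.0

    def test_two_seeds_arithmetic_mean(self):
        out = aggregate_over_seeds([np.array([10.0, 20.0]), np.array([30.0])], "mean")
        assert out == pytest.approx(20.0)

    def test_pooled_count_conserved(self):
        pooled = aggregate_over_seeds(
            [np.arange(5.0), np.arange(3.0), np.arange(7.0)], "pooled"
        )
        assert pooled.size == 15

    def test_unknown_policy_raises(self):
        with pytest.raises(ValueError):
            aggregate_over_seeds([np.array([1.0])], "median")


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 199.9), min_size=1, max_size=60))
def test_topa_histogram_conservation_property(offsets):
    counts, edges = topa_histogram(np.array(offsets), 200.0, bin_width=10.0)
    assert counts.sum() == len(offsets)
    assert edges[0] == 0.0 and edges[-1] >= 200.0


def test_score_trace_bundles_global_peak():
    trace = np.zeros(400)
    trace[120] = 1.0  # tallest peak, second window
    trace[30] = 0.5
    res = score_trace(trace, [(0.0, 100.0), (100.0, 200.0)], 1.0, 100.0)
    assert res.n_windows == 2
    assert res.global_offset == 20.0
    assert res.global_zscore == pytest.approx(peak_zscore(trace, 1.0))
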