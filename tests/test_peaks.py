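import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msipeaks import Hyperparameters, find_peaks
from msipeaks.peaks import (
    detect_candidate_peaks,
    pad_and_densify,
    relative_heights,
    smooth,
)

from .conftest import random_histogram
from .oracles import detect_peaks_oracle


class TestPadAndDensify:
    def test_single_bin_padded_both_sides(self, make_hist):
        series, offset = pad_and_densify(make_hist({21: 3}))
        assert series.tolist() == [0, 3, 0]
        assert offset == 20

    def test_gap_filled_with_zero(self, make_hist):
        series, offset = pad_and_densify(make_hist({20: 1, 22: 5}))
        assert series.tolist() == [0, 1, 0, 5, 0]
        assert offset == 19

    def test_empty_histogram_flagged(self, make_hist):
        series, offset = pad_and_densify(make_hist({}))
        assert series.size == 0 and offset is None


class TestSmooth:
    def test_spike_spreads_to_width_three(self):
        assert smooth([0, 6, 0]).tolist() == [0, 2, 2, 2, 0]

    def test_window3_means_hand_computed(self):
        assert smooth([0, 3, 3, 3, 0]).tolist() == [0, 1, 2, 3, 2, 1, 0]

    def test_all_zero_stays_zero(self):
        assert smooth([0, 0, 0]).tolist() == [0] * 5

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        values=st.lists(st.integers(min_value=0, max_value=10_000),
                        min_size=1, max_size=40)
    )
    def test_mass_conserved_exactly(self, values):
        # Each smoothed value is (integer sum of 3 neighbors)/3; reconstruct
        # the integer numerators to check conservation in exact arithmetic.
        smoothed = smooth(values)
        numerators = np.rint(smoothed * 3).astype(int)
        assert np.allclose(smoothed * 3, numerators)
        assert numerators.sum() == 3 * sum(values)


class TestDetect:
    @pytest.mark.parametrize(
        "series, expected",
        [
            ([0, 1, 3, 1, 0], [(2, 3.0)]),
            ([0, 5, 5, 5, 0], [(1, 5.0)]),
            ([0, 2, 1, 4, 1, 0], [(1, 2.0), (3, 4.0)]),
            ([0, 0, 0], []),
        ],
    )
    def test_examples(self, series, expected):
        assert detect_candidate_peaks(series) == expected

    def test_matches_brute_force_oracle_on_random_series(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 30))
            series = rng.integers(0, 6, size=n).tolist()
            series = [0] + series + [0]
            assert detect_candidate_peaks(series) == detect_peaks_oracle(series)


class TestRelativeHeights:
    def test_mean_nonzero_bins_convention(self):
        series = [0, 2, 10, 3, 0]  # nonzero mean 5
        annotated = relative_heights([(2, 10.0)], series, "mean_nonzero_bins")
        assert annotated == [(2, 10.0, 2.0)]

    def test_peak_sum_single_candidate_normalizes_to_one(self):
        annotated = relative_heights([(2, 7.0)], [0, 0, 7, 0], "peak_sum")
        assert annotated == [(2, 7.0, 1.0)]

    def test_peak_sum_equal_candidates_split_evenly(self):
        annotated = relative_heights(
            [(1, 4.0), (3, 4.0)], [0, 4, 0, 4, 0], "peak_sum"
        )
        assert [rh for _, _, rh in annotated] == [0.5, 0.5]

    def test_all_zero_series_is_an_error(self):
        with pytest.raises(ValueError, match="no depth"):
            relative_heights([], [0, 0, 0], "mean_nonzero_bins")


class TestFindPeaks:
    def test_lone_allele_without_smoothing_sits_at_its_length(self, make_hist):
        ps = find_peaks(make_hist({25: 100}), Hyperparameters(smoothing=False))
        assert ps.positions == [25]

    def test_lone_allele_with_smoothing_collapses_plateau_leftmost(self, make_hist):
        # Smoothing turns an isolated spike into an exact 3-bin plateau;
        # the plateau rule reports its leftmost bin, one unit below.
        ps = find_peaks(make_hist({25: 100}), Hyperparameters(smoothing=True))
        assert len(ps) == 1
        assert ps.positions == [24]

    def test_empty_histogram_gives_empty_peak_set(self, make_hist):
        ps = find_peaks(make_hist({}))
        assert len(ps) == 0 and ps.total_reads == 0

    def test_stutter_broadened_bimodal_recovers_both_modes(self, make_hist):
        from msipeaks.simulate import AlleleModel, simulate_histogram

        hist = simulate_histogram(
            [AlleleModel(25), AlleleModel(18, depth=300)], seed=11
        )
        ps = find_peaks(hist, Hyperparameters(smoothing=True, r_h=0.2))
        assert ps.positions == [18, 25]

    def test_raising_threshold_past_minor_mode_drops_it(self, make_hist):
        from msipeaks.simulate import AlleleModel, simulate_histogram

        hist = simulate_histogram(
            [AlleleModel(25), AlleleModel(18, depth=300)], seed=11
        )
        minor = min(
            find_peaks(hist, Hyperparameters(True, 0.2)).peaks,
            key=lambda p: p.relative_height,
        )
        ps = find_peaks(hist, Hyperparameters(True, minor.relative_height + 0.05))
        assert ps.positions == [25]

    def test_peak_count_non_increasing_in_threshold(self, rng):
        grid = [k / 10 for k in range(1, 31)]
        for _ in range(50):
            hist = random_histogram(rng)
            for smoothing in (True, False):
                counts = [
                    len(find_peaks(hist, Hyperparameters(smoothing, r)))
                    for r in grid
                ]
                assert counts == sorted(counts, reverse=True)

    def test_positions_invariant_under_uniform_scaling(self, rng, make_hist):
        for mode in ("mean_nonzero_bins", "peak_sum"):
            for _ in range(20):
                hist = random_histogram(rng)
                scaled = make_hist({k: v * 7 for k, v in hist.counts.items()})
                for smoothing in (True, False):
                    hp = Hyperparameters(smoothing, 0.2, mode)
                    assert (
                        find_peaks(hist, hp).positions
                        == find_peaks(scaled, hp).positions
                    )

    def test_noise_suppression_smoothing_removes_single_read_peaks(self, make_hist):
        # A dominant allele plus isolated 1-read stray bins: at default
        # settings the strays smooth into sub-threshold ripples while the
        # main mode survives.
        hist = make_hist({25: 400, 24: 40, 26: 10, 35: 1, 12: 1})
        ps = find_peaks(hist, Hyperparameters(smoothing=True, r_h=0.2))
        assert len(ps) == 1
        assert ps.peaks[0].position == 25

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            Hyperparameters(r_h=0.0)
        with pytest.raises(ValueError):
            Hyperparameters(denominator_mode="bogus")
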