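"""Tests of mixed-peak detection: windows, ratios, noise gate, factor f."""

import numpy as np
import pytest

from sangerbatch.peakcall import (
    detect_mixed_peaks,
    noise_threshold,
    peak_window,
    secondary_peak_metrics,
)
from sangerbatch.simulate import MIXED_PEAK, PlantedEvent, SimParams, simulate_chromatogram
from sangerbatch.trace_io import BASES, Chromatogram


def flat_trace(bases, positions, length, channel_values=None, qualities=None):
    channels = {b: np.zeros(length, dtype=int) for b in BASES}
    if channel_values:
        for b, arr in channel_values.items():
            channels[b] = np.asarray(arr, dtype=int)
    return Chromatogram(
        "t", "GATC", channels, np.asarray(positions), bases,
        np.asarray(qualities if qualities is not None else [50] * len(bases)),
    )


def peak_shape(length, centre, values):
    """Place an explicit symmetric peak (list of values, centre at middle)."""
    arr = np.zeros(length, dtype=int)
    half = len(values) // 2
    arr[centre - half : centre - half + len(values)] = values
    return arr


class TestPeakWindow:
    def test_midpoints(self):
        c = flat_trace("AAA", [10, 20, 30], 40)
        w = peak_window(c, 1)
        assert (w.lo, w.hi) == (15, 25)

    def test_single_peak_spans_whole_signal(self):
        c = flat_trace("A", [10], 40)
        w = peak_window(c, 0)
        assert (w.lo, w.hi) == (0, 40)

    def test_out_of_range_index(self):
        c = flat_trace("A", [10], 40)
        with pytest.raises(IndexError):
            peak_window(c, 1)

    @pytest.mark.parametrize(
        "positions,index,expected",
        [
            # fractional midpoints round toward the centre peak
            ([10, 11], 0, (0, 11)),
            ([10, 11], 1, (11, 20)),
            ([10, 13], 0, (0, 11)),
            ([10, 13], 1, (12, 20)),
            ([10, 20, 30], 0, (0, 15)),
            ([10, 20, 30], 2, (25, 40)),
        ],
    )
    def test_rounding_convention(self, positions, index, expected):
        c = flat_trace("A" * len(positions), positions, 10 * (positions[-1] // 10 + 1))
        w = peak_window(c, index)
        assert (w.lo, w.hi) == expected
        assert w.lo <= w.centre < w.hi


class TestSecondaryPeakMetrics:
    def test_zero_candidate_channel(self):
        c = flat_trace("A", [10], 20, {"A": peak_shape(20, 10, [100, 500, 100])})
        assert secondary_peak_metrics(c, 0, "G") == (0.0, 0.0, False)

    def test_candidate_equal_to_main(self):
        shape = peak_shape(20, 10, [100, 500, 100])
        c = flat_trace("A", [10], 20, {"A": shape, "G": shape.copy()})
        area, height, concave = secondary_peak_metrics(c, 0, "G")
        assert area == 1.0 and height == 1.0 and concave

    def test_gaussian_pair_recovers_amplitude_ratio(self):
        x = np.arange(200, dtype=float)
        main = np.rint(1000 * np.exp(-0.5 * ((x - 100) / 4) ** 2)).astype(int)
        sec = np.rint(300 * np.exp(-0.5 * ((x - 100) / 4) ** 2)).astype(int)
        c = flat_trace("A", [100], 200, {"A": main, "C": sec})
        area, height, concave = secondary_peak_metrics(c, 0, "C")
        assert area == pytest.approx(0.3, abs=0.01)
        assert height == pytest.approx(0.3, abs=0.01)
        assert concave

    def test_degenerate_main_peak(self, caplog):
        c = flat_trace("A", [10], 20, {"C": peak_shape(20, 10, [1, 2, 1])})
        with caplog.at_level("WARNING"):
            assert secondary_peak_metrics(c, 0, "C") == (0.0, 0.0, False)
        assert "degenerate" in caplog.text

    def test_convex_candidate_rejected(self):
        # candidate dips at the main-peak centre: shoulders of two
        # neighbouring peaks, not a secondary peak underneath
        c = flat_trace("A", [10], 20, {
            "A": peak_shape(20, 10, [100, 500, 100]),
            "C": peak_shape(20, 10, [300, 200, 100, 20, 0, 20, 100, 200, 300]),
        })
        *_, concave = secondary_peak_metrics(c, 0, "C")
        assert not concave


class TestNoiseThreshold:
    def test_noiseless_trace_gives_zero(self):
        c = simulate_chromatogram("ACGTACGT", SimParams(noise_sd=0))
        thr = noise_threshold(c)
        assert all(v == 0.0 for v in thr.values())

    def test_constant_background(self):
        length = 40
        channels = {b: np.full(length, 10, dtype=int) for b in BASES}
        channels["A"] = peak_shape(length, 10, [100, 900, 100]) + 10
        c = Chromatogram("t", "GATC", channels, np.array([10, 30]), "AA",
                         np.array([50, 50]))
        thr = noise_threshold(c, k=2.0)
        assert thr["C"] == 20.0 and thr["G"] == 20.0 and thr["T"] == 20.0

    def test_median_robust_to_minority_mixed_peaks(self):
        """Planting mixed peaks at <50% of positions leaves the median
        off-peak background unchanged (brute-force median check)."""
        seq = "ACGTACGTACGTACGTACGT"
        mixed = [PlantedEvent(MIXED_PEAK, i, "A") for i in (1, 2)]  # 2 of 20
        clean = simulate_chromatogram(seq, SimParams(noise_sd=0))
        planted = simulate_chromatogram(seq, SimParams(noise_sd=0), planted=mixed)
        med_clean = np.median([clean.channels["A"][p] for p, b in
                               zip(clean.peak_positions, clean.bases) if b != "A"])
        med_planted = np.median([planted.channels["A"][p] for p, b in
                                 zip(planted.peak_positions, planted.bases) if b != "A"])
        assert med_planted == med_clean
        assert noise_threshold(planted)["A"] == 2.0 * med_planted

    def test_no_called_bases_is_error(self):
        c = flat_trace("", [], 20)
        with pytest.raises(ValueError):
            noise_threshold(c)


def boundary_trace(ratio_milli: int) -> Chromatogram:
    """A trace whose secondary peak has area and height ratio exactly
    ratio_milli/1000, by construction with integer signal values."""
    length = 60
    main = [1000, 2000, 1000]
    sec = [ratio_milli, 2 * ratio_milli, ratio_milli]
    channels = {b: np.zeros(length, dtype=int) for b in BASES}
    channels["A"] = peak_shape(length, 10, main) + peak_shape(length, 30, main) + peak_shape(length, 50, main)
    channels["C"] = peak_shape(length, 30, sec)
    return Chromatogram("b", "GATC", channels, np.array([10, 30, 50]), "AAA",
                        np.array([50, 50, 50]))


class TestDetectMixedPeaks:
    def test_boundary_inclusive_at_default_factor(self):
        """'at least f times' is inclusive: an exact 0.15 ratio is reported."""
        calls = detect_mixed_peaks(boundary_trace(150), f=0.15)
        assert [(c.base_index, c.secondary_base) for c in calls] == [(1, "C")]
        assert calls[0].area_ratio == pytest.approx(0.15)
        assert calls[0].height_ratio == pytest.approx(0.15)

    def test_just_below_boundary_not_reported(self):
        assert detect_mixed_peaks(boundary_trace(149), f=0.15) == []

    def test_invalid_factor_rejected(self):
        for f in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                detect_mixed_peaks(boundary_trace(400), f=f)

    def test_planted_peaks_recovered_exactly(self):
        """Three planted secondary peaks at ratio 0.4 over baseline noise
        are exactly the reported positions; cross-checked against a
        brute-force evaluation of the criterion at every position."""
        seq = "ACGTACGTACGTACGTACGTACGTACGTAC"
        planted_at = [3, 11, 22]
        events = [
            PlantedEvent(MIXED_PEAK, i, "A" if seq[i] != "A" else "C", ratio=0.4)
            for i in planted_at
        ]
        c = simulate_chromatogram(seq, SimParams(noise_sd=10, seed=5), planted=events)
        calls = detect_mixed_peaks(c, f=0.15)
        assert [call.base_index for call in calls] == planted_at

        # brute force: evaluate the full criterion at every (position, channel)
        gates = noise_threshold(c, k=2.0)
        expected = set()
        for i, base in enumerate(c.bases):
            for ch in BASES:
                if ch == base:
                    continue
                area, height, concave = secondary_peak_metrics(c, i, ch)
                w = peak_window(c, i)
                cand_height = c.channels[ch][w.lo : w.hi].max()
                if area >= 0.15 and height >= 0.15 and concave and cand_height > gates[ch]:
                    expected.add(i)
        assert {call.base_index for call in calls} == expected

    def test_monotone_in_f(self):
        """Raising f can only shrink the detected set."""
        seq = "ACGTACGTACGTACGTACGTACGTACGTAC"
        events = [
            PlantedEvent(MIXED_PEAK, i, "A" if seq[i] != "A" else "C", ratio=r)
            for i, r in [(2, 0.08), (8, 0.2), (15, 0.45), (24, 0.8)]
        ]
        c = simulate_chromatogram(seq, SimParams(noise_sd=5, seed=9), planted=events)
        detected = [
            {call.base_index for call in detect_mixed_peaks(c, f=f)}
            for f in (0.05, 0.15, 0.3, 0.6)
        ]
        for smaller_f, larger_f in zip(detected, detected[1:]):
            assert larger_f <= smaller_f

    def test_never_reports_called_channel(self, rng):
        from conftest import random_chromatogram

        for _ in range(10):
            c = random_chromatogram(rng, n_bases=12)
            for call in detect_mixed_peaks(c, f=0.15):
                assert call.secondary_base != call.primary_base

    def test_deterministic(self):
        c = simulate_chromatogram("ACGTACGT", SimParams(seed=3),
                                  planted=[PlantedEvent(MIXED_PEAK, 2, "A", ratio=0.5)])
        assert detect_mixed_peaks(c) == detect_mixed_peaks(c)
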