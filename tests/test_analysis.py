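"""Peak detection, mode classification and hopping statistics."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nfkb_modehop import (classify_modes, detect_peaks, mode_statistics,
                          period_views, transition_heatmap)
from nfkb_modehop.analysis import fraction_near_integer_multiple
from nfkb_modehop.errors import InsufficientDataError, InvalidInputError

HALF = Fraction(1, 2)
ONE = Fraction(1)
TWO = Fraction(2)


def test_sinusoid_peak_spacing():
    t = np.arange(0.0, 2000.0, 5.0)
    v = np.sin(2 * np.pi * t / 100.0)
    peaks = detect_peaks(t, v, smooth_window=1)
    assert len(peaks) >= 18
    assert np.all(np.abs(peaks.intervals - 100.0) <= 5.0)


def test_constant_trace_yields_no_peaks():
    t = np.arange(0.0, 500.0, 5.0)
    peaks = detect_peaks(t, np.full_like(t, 3.7))
    assert len(peaks) == 0


def test_small_secondary_bumps_are_filtered():
    """Bumps at 5% of the maximum fall below the 10%-of-max height filter."""
    t = np.arange(0.0, 3000.0, 5.0)
    main = np.clip(np.sin(2 * np.pi * t / 200.0), 0, None)
    bumps = 0.05 * np.clip(np.sin(2 * np.pi * (t - 100.0) / 200.0), 0, None)
    peaks = detect_peaks(t, main + bumps, smooth_window=1, min_separation=20.0)
    assert np.all(np.abs(peaks.intervals - 200.0) <= 5.0)


def test_close_peaks_keep_the_higher_one():
    t = np.arange(0.0, 300.0, 1.0)
    v = np.exp(-0.5 * ((t - 100) / 4.0) ** 2) + 0.8 * np.exp(-0.5 * ((t - 110) / 4.0) ** 2)
    peaks = detect_peaks(t, v, smooth_window=1, min_separation=20.0)
    assert len(peaks) == 1
    assert peaks.peak_times[0] == pytest.approx(100.0, abs=2.0)


@settings(max_examples=50, deadline=None)
@given(scale=st.floats(0.01, 100.0), offset=st.floats(-50.0, 50.0))
def test_detection_invariant_to_affine_rescaling(scale, offset):
    t = np.arange(0.0, 1500.0, 5.0)
    v = np.sin(2 * np.pi * t / 90.0) + 0.3 * np.sin(2 * np.pi * t / 37.0)
    base = detect_peaks(t, v)
    rescaled = detect_peaks(t, scale * v + offset)
    assert np.array_equal(base.peak_times, rescaled.peak_times)


def test_non_monotone_times_rejected():
    with pytest.raises(InvalidInputError):
        detect_peaks([0.0, 10.0, 5.0], [1.0, 2.0, 1.0])


@pytest.mark.parametrize(
    "period, expected",
    [(90.0, HALF), (182.0, ONE), (135.0, None), (360.0, TWO), (59.0, Fraction(1, 3))],
)
def test_interval_snaps_to_nearest_allowed_ratio(period, expected):
    modes = classify_modes([period], tnf_period=180.0)
    assert modes.labels == [expected]


@settings(max_examples=50, deadline=None)
@given(c=st.floats(0.01, 1000.0))
def test_classification_is_scale_invariant(c):
    intervals = [90.0, 182.0, 135.0, 250.0]
    a = classify_modes(intervals, 180.0)
    b = classify_modes([c * p for p in intervals], c * 180.0)
    assert a.labels == b.labels


def test_empty_intervals_give_empty_sequence():
    assert len(classify_modes([], 180.0)) == 0


def test_alternating_labels_count_transitions():
    modes = classify_modes([90, 182, 90, 182], 180.0)
    stats = mode_statistics(modes)
    assert stats["n_transitions"] == 3
    assert stats["transitions_per_1000"] == pytest.approx(750.0)


def test_single_mode_has_no_transitions():
    modes = classify_modes([90, 90, 90, 90], 180.0)
    stats = mode_statistics(modes)
    assert stats["n_transitions"] == 0
    assert stats["occupancy"] == {HALF: 1.0}


def test_unentrained_breaks_dwells_without_counting_transitions():
    # 90 -> (135: unentrained) -> 90 is a broken dwell, not a hop
    modes = classify_modes([90, 135, 90, 90], 180.0)
    stats = mode_statistics(modes)
    assert stats["n_transitions"] == 0
    assert stats["dwell_lengths"][HALF] == [1, 2]


@settings(max_examples=100, deadline=None)
@given(st.lists(st.sampled_from([85.0, 95.0, 135.0, 180.0, 365.0]), min_size=1, max_size=50))
def test_occupancy_always_sums_to_one(intervals):
    stats = mode_statistics(classify_modes(intervals, 180.0))
    assert sum(stats["occupancy"].values()) == pytest.approx(1.0)


def test_period_histogram_and_return_pairs():
    view = period_views([90.0] * 10, 180.0, bin_width=5.0)
    assert np.count_nonzero(view["hist_counts"]) == 1
    assert np.all(view["lag1_pairs"] == 90.0)
    mixed = period_views([90.0, 180.0] * 5, 180.0, bin_width=5.0)
    assert np.count_nonzero(mixed["hist_counts"]) == 2
    # pairs preserve ordering
    assert mixed["lag1_pairs"][0].tolist() == [90.0, 180.0]


def test_fraction_near_integer_multiple_counts_correctly():
    intervals = [50.0, 101.0, 148.0, 75.0]  # 75 is ~halfway between 50 and 100
    frac = fraction_near_integer_multiple(intervals, 50.0, rel_tol=0.15)
    assert frac == pytest.approx(0.75)


def test_heatmap_of_strict_alternation_is_off_diagonal():
    modes = classify_modes([90, 182, 90, 182, 90], 180.0)
    hm = transition_heatmap(modes)
    assert hm.loc["1/2", "1"] == 1.0
    assert hm.loc["1", "1/2"] == 1.0
    assert hm.loc["1/2", "1/2"] == 0.0


def test_heatmap_single_mode_and_row_normalisation():
    hm = transition_heatmap(classify_modes([90, 90, 90], 180.0))
    assert hm.shape == (1, 1)
    assert hm.iloc[0, 0] == 1.0
    modes = classify_modes([90, 182, 90, 90, 182, 365], 180.0)
    hm2 = transition_heatmap(modes)
    assert np.allclose(hm2.sum(axis=1), 1.0, atol=1e-12)


def test_heatmap_requires_adjacent_entrained_pairs():
    with pytest.raises(InsufficientDataError):
        transition_heatmap(classify_modes([135.0, 135.0], 180.0))
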