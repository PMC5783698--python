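"""Arnold tongue classification, multistability and chaos diagnostics."""

from fractions import Fraction

import numpy as np
import pytest

from nfkb_modehop import (PeakSeries, TNFSignal, asymptotic_ratio,
                          detect_period_doubling, lyapunov_benettin,
                          multistability_scan, tongue_scan)
from nfkb_modehop.errors import InsufficientDataError, InvalidInputError
from nfkb_modehop.tongues import ScanSettings

FAST = ScanSettings(transient=10000.0, horizon_cycles=20, dt=0.02)


def test_resonant_forcing_locks_one_to_one(params):
    r, why = asymptotic_ratio(params, TNFSignal(period=100.0, amplitude=0.1), settings=FAST)
    assert r == Fraction(1)
    assert why == "locked"


def test_zero_amplitude_is_not_locked(params):
    # the free-running period is incommensurate with an arbitrary grid period
    r, why = asymptotic_ratio(params, TNFSignal(period=100.0, amplitude=0.0), settings=FAST)
    assert r is None


def test_quasiperiodic_drift_is_rejected(params):
    """Weak forcing at T=180 leaves the oscillator near its natural period;
    the rotation number does not equal 1/2, so no lock is reported."""
    r, why = asymptotic_ratio(params, TNFSignal(period=180.0, amplitude=0.05), settings=FAST)
    assert r is None


def test_subharmonic_lock_at_180(params):
    r, why = asymptotic_ratio(params, TNFSignal(period=180.0, amplitude=0.15), settings=FAST)
    assert r == Fraction(1, 2)


def test_tongue_scan_shape_and_zero_amplitude_row(params):
    amap = tongue_scan([90.0, 100.0], [0.0, 0.1], params, FAST)
    df = amap.to_frame()
    assert len(df) == 4
    # A = 0 cells cannot lock
    assert (df[df.amplitude == 0.0]["ratio"] == "unlocked").all()
    # cells evaluated independently: direct call gives the same answer
    r, _ = asymptotic_ratio(params, TNFSignal(period=100.0, amplitude=0.1), settings=FAST)
    assert str(amap.ratio[1, 1]) == str(r)


def test_overlap_point_is_multistable(params):
    """At (T=50, A=0.1) different initial conditions settle into different
    locked states (coexisting limit cycles, Fig-3-style overlap region)."""
    found = multistability_scan(TNFSignal(period=50.0, amplitude=0.1), params,
                                n_init=20, seed=7, settings=FAST)
    assert len(found) >= 2
    assert Fraction(2) in found


def test_single_init_finds_at_most_one_mode(params):
    found = multistability_scan(TNFSignal(period=50.0, amplitude=0.1), params,
                                n_init=1, seed=0, settings=FAST)
    assert len(found) <= 1


def test_lyapunov_positive_in_chaotic_regime(params):
    lam, se = lyapunov_benettin(params, TNFSignal(period=50.0, amplitude=0.8),
                                t_total=6000.0, transient=2000.0)
    assert lam > 1e-3
    assert lam - 2 * se > 0.0


def test_lyapunov_nonpositive_when_entrained(params):
    lam, _ = lyapunov_benettin(params, TNFSignal(period=100.0, amplitude=0.1),
                               t_total=8000.0, transient=6000.0)
    assert lam < 1e-3  # contracting (up to numerical noise around 0)


def test_degenerate_perturbation_rejected(params):
    with pytest.raises(InvalidInputError):
        lyapunov_benettin(params, TNFSignal.constant(), delta0=0.0)


def _peaks(heights):
    times = 90.0 * np.arange(len(heights))
    return PeakSeries(times, np.asarray(heights, dtype=float))


def test_period_doubling_orders():
    assert detect_period_doubling(_peaks([1.0] * 10)) == 1
    assert detect_period_doubling(_peaks([1.0, 0.7] * 6)) == 2
    assert detect_period_doubling(_peaks([1.0, 0.7, 0.9, 0.5] * 4)) == 4


def test_random_heights_are_aperiodic(rng):
    heights = 1.0 + rng.uniform(-0.4, 0.4, size=24)
    assert detect_period_doubling(_peaks(heights)) == "aperiodic"


def test_period_doubling_needs_eight_peaks():
    with pytest.raises(InsufficientDataError):
        detect_period_doubling(_peaks([1.0, 0.7] * 3))


def test_subharmonic_attractor_shows_peak_alternation(params, entrained_trajectory):
    """The 1:2-locked orbit alternates between two peak heights (one TNF
    cycle drives two unequal NF-κB excursions)."""
    from nfkb_modehop import detect_peaks

    peaks = detect_peaks(entrained_trajectory.times, entrained_trajectory.nn,
                         smooth_window=1, min_separation=40.0)
    assert detect_period_doubling(peaks) == 2
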