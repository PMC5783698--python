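"""Gillespie engine: channel structure, reproducibility, noise scaling."""

import numpy as np
import pytest

from nfkb_modehop import (CountState, SSAConfig, TNFSignal, build_propensities,
                          integrate_rk4, simulate_gillespie)
from nfkb_modehop.errors import InvalidStateError
from nfkb_modehop.stochastic import volume_to_factor


@pytest.fixture(scope="module")
def cfg():
    return SSAConfig(volume=1e-15, seed=0, t_end=100.0)


def test_term_per_channel_mode_has_ten_channels(params, cfg):
    counts = CountState.from_concentrations(np.array([0.1, 0.2, 0.3, 0.4, 0.5]), cfg.f)
    a, stoich = build_propensities(counts, params, 1.0, cfg)
    assert a.shape == (10,)
    assert len(stoich) == 10


def test_physical_mode_fuses_conversion_channel(params):
    cfg = SSAConfig(volume=1e-15, channel_mode="physical")
    counts = CountState.from_concentrations(np.array([0.1, 0.2, 0.3, 0.4, 0.5]), cfg.f)
    a, stoich = build_propensities(counts, params, 1.0, cfg)
    assert a.shape == (9,)
    # the fused channel moves one molecule from IKKa to IKKi atomically
    assert stoich[7] == ((3, -1), (4, +1))


def test_each_term_channel_changes_one_species_by_one(params, cfg):
    counts = CountState.from_concentrations(np.array([0.1, 0.2, 0.3, 0.4, 0.5]), cfg.f)
    _, stoich = build_propensities(counts, params, 1.0, cfg)
    assert all(delta in (-1, +1) for _, delta in stoich)
    # two channels per species: one producing, one consuming
    for k in range(5):
        deltas = sorted(d for s, d in stoich if s == k)
        assert deltas == [-1, +1]


def test_import_propensity_from_empty_cell(params, cfg):
    """Only NF-κB import can fire from an empty cell: rate kNin·Ntot·f."""
    counts = CountState(np.zeros(5, dtype=int), cfg.f)
    a, _ = build_propensities(counts, params, 1.0, cfg)
    assert a[0] == pytest.approx(params.kNin * params.Ntot * cfg.f)
    # IKK activation is the only other nonzero channel (full neutral pool)
    assert a[6] == pytest.approx(params.ka * params.IKKtot * cfg.f)
    assert np.count_nonzero(a) == 2


def test_import_blocked_at_full_nucleus(params, cfg):
    n_ntot = int(round(params.Ntot * cfg.f))
    counts = CountState(np.array([n_ntot, 0, 0, 0, 0]), cfg.f)
    a, _ = build_propensities(counts, params, 1.0, cfg)
    assert a[0] == 0.0


def test_negative_counts_rejected(cfg):
    with pytest.raises(InvalidStateError):
        CountState(np.array([-1, 0, 0, 0, 0]), cfg.f)


def test_same_seed_reproduces_trajectory(params):
    sig = TNFSignal(period=50.0, amplitude=0.1)
    c = SSAConfig(volume=1e-15, seed=11, t_end=500.0)
    a = simulate_gillespie(None, params, sig, c)
    b = simulate_gillespie(None, params, sig, c)
    assert np.array_equal(a.states, b.states)
    assert a.meta["n_events"] == b.meta["n_events"]
    different = simulate_gillespie(None, params, sig,
                                   SSAConfig(volume=1e-15, seed=12, t_end=500.0))
    assert not np.array_equal(a.states, different.states)


def test_counts_stay_nonnegative_and_within_pools(params):
    for mode in ("term_per_channel", "physical"):
        c = SSAConfig(volume=1e-15, seed=3, t_end=2000.0, channel_mode=mode)
        traj = simulate_gillespie(None, params, TNFSignal.constant(), c)
        n_ntot = round(params.Ntot * c.f)
        n_ikktot = round(params.IKKtot * c.f)
        assert np.all(traj.states >= 0)
        assert np.all(traj.states[:, 0] <= n_ntot)
        assert np.all(traj.states[:, 3] + traj.states[:, 4] <= n_ikktot)


def test_conversion_factor_is_avogadro_scaled():
    assert volume_to_factor(1e-15) == pytest.approx(602.214076, rel=1e-9)


def test_low_noise_ensemble_mean_tracks_ode(params):
    """At V = 1e-13 L the replicate mean follows the deterministic trajectory.

    The pointwise comparison is made inside the phase-coherence window
    (before slow phase diffusion dephases replicates from the deterministic
    clock); tolerance 10% of the oscillation amplitude.
    """
    const = TNFSignal.constant()
    reps = []
    for s in range(20):
        c = SSAConfig(volume=1e-13, seed=100 + s, t_end=1000.0, record_every=5.0)
        reps.append(simulate_gillespie(None, params, const, c).nn)
    mean = np.mean(reps, axis=0)
    ode = integrate_rk4(None, params, const, t_end=1000.0, record_every=5.0)
    window = ode.times >= 500.0
    amplitude = ode.nn[window].max() - ode.nn[window].min()
    deviation = np.abs(mean[window] - ode.nn[window]).max()
    assert deviation < 0.10 * amplitude


def test_intrinsic_noise_decreases_with_volume(params):
    """Fast-fluctuation variance of Nn falls monotonically across volumes.

    Short-time increments isolate the stochastic component from the
    deterministic spike shape (which a moving-average detrend would leak).
    """
    variances = []
    for volume in (1e-15, 2e-15, 5e-15, 15e-15):
        c = SSAConfig(volume=volume, seed=9, t_end=3000.0, record_every=0.25)
        traj = simulate_gillespie(None, params, TNFSignal.constant(), c).after(500.0)
        variances.append(np.var(np.diff(traj.nn)))
    assert all(a > b for a, b in zip(variances, variances[1:]))
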