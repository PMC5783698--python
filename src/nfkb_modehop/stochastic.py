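"""Exact Gillespie (SSA) simulation of the NF-κB model at a chosen cell volume.

Noise strength is set by molecule numbers: concentrations (μM) convert to
counts via f = N_A · V · 10⁻⁶ molecules per μM, so smaller volumes mean fewer
molecules and larger relative fluctuations while average concentrations stay
the same.

Reaction channels follow the ODE terms one-to-one: each of the 10 terms in
the five rate equations becomes one channel changing a single species by ±1,
with propensity equal to the deterministic term evaluated at the current
concentrations times f.  This decouples the IKKa→IKKi conversion (the ki·IKKa
term appears in two equations) into two unary channels; the alternative
``physical`` mode fuses them into one conversion channel so the IKK pool is
conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .deterministic import Trajectory
from .errors import InvalidInputError, InvalidStateError
from .model import ModelParameters, ModelState, TNFSignal

__all__ = ["SSAConfig", "CountState", "build_propensities", "simulate_gillespie",
           "volume_to_factor", "AVOGADRO"]

AVOGADRO = 6.02214076e23

#: channel -> (species index, delta) for term-per-channel mode
STOICH_TERM = (
    (0, +1), (0, -1),   # Nn import / export
    (1, +1), (1, -1),   # Im production / decay
    (2, +1), (2, -1),   # I translation / degradation
    (3, +1), (3, -1),   # IKKa activation / deactivation (term of eq. 4)
    (4, +1), (4, -1),   # IKKi gain (term of eq. 5) / recycling
)

#: physical mode: channels 0-6 as above, 7 = IKKa→IKKi conversion, 8 = IKKi recycling
STOICH_PHYSICAL = STOICH_TERM[:7] + (((3, -1), (4, +1)), (4, -1))


def volume_to_factor(volume: float) -> float:
    """Molecules per μM at the given volume (liters)."""
    if not volume > 0:
        raise InvalidInputError(f"volume must be > 0, got {volume!r}")
    return AVOGADRO * volume * 1e-6


@dataclass(frozen=True)
class SSAConfig:
    """Run configuration for the stochastic engine."""

    volume: float = 1e-15
    seed: int = 0
    channel_mode: str = "term_per_channel"
    t_end: float = 3000.0
    record_every: float = 1.0

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise InvalidInputError("volume must be > 0")
        if not self.record_every > 0:
            raise InvalidInputError("record_every must be > 0")
        if self.channel_mode not in ("term_per_channel", "physical"):
            raise InvalidInputError(f"unknown channel_mode {self.channel_mode!r}")

    @property
    def f(self) -> float:
        return volume_to_factor(self.volume)


@dataclass
class CountState:
    """Integer molecule counts of the five species plus the conversion factor."""

    counts: np.ndarray
    f: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (5,):
            raise InvalidStateError("counts must have 5 entries")
        if np.any(self.counts < 0):
            raise InvalidStateError(f"negative molecule count: {self.counts}")

    @classmethod
    def from_concentrations(cls, state: ModelState | np.ndarray, f: float) -> "CountState":
        y = state.as_array() if isinstance(state, ModelState) else np.asarray(state, float)
        return cls(np.rint(y * f).astype(np.int64), f)  # rint: ties to even

    def concentrations(self) -> np.ndarray:
        return self.counts / self.f


def build_propensities(
    counts: CountState,
    params: ModelParameters,
    tnf: float,
    config: SSAConfig,
) -> tuple[np.ndarray, tuple]:
    """Propensity vector (events·min⁻¹) and stoichiometry table.

    Exactly 10 channels in the default term-per-channel mode, 9 in physical
    mode.  Propensity of term j is the deterministic rate of that term at the
    concentrations counts/f, scaled by f; channels with an exhausted reactant
    or a saturated conserved pool get zero propensity.
    """
    if np.any(counts.counts < 0):
        raise InvalidStateError("negative molecule count")
    physical = config.channel_mode == "physical"
    p = params.as_array()
    f = counts.f
    a = np.zeros(10)
    n_ntot = int(round(params.Ntot * f))
    n_ikktot = int(round(params.IKKtot * f))
    _kernels._propensities(a, counts.counts, p, tnf, f, n_ntot, n_ikktot, physical)
    if physical:
        return a[:9].copy(), STOICH_PHYSICAL
    return a, STOICH_TERM


def simulate_gillespie(
    init: ModelState | np.ndarray | None = None,
    params: ModelParameters | None = None,
    signal: TNFSignal | None = None,
    config: SSAConfig | None = None,
) -> Trajectory:
    """Exact SSA run, recorded on a uniform grid by sample-and-hold.

    The square-wave forcing is piecewise constant, so propensities are
    constant between switching times; waiting times are drawn per segment and
    redrawn whenever the clock is advanced to a switch, which keeps the
    algorithm exact for time-varying input.  A fully stalled system (zero
    total propensity, constant forcing) is reported via
    ``meta['stalled']`` rather than raised.
    """
    from .deterministic import DEFAULT_INIT

    params = params or ModelParameters()
    signal = signal or TNFSignal.constant()
    config = config or SSAConfig()
    if init is None:
        init = DEFAULT_INIT
    f = config.f
    n0 = CountState.from_concentrations(init, f)
    physical = config.channel_mode == "physical"
    times, out, n_events, stalled = _kernels.gillespie_kernel(
        n0.counts, params.as_array(), signal.as_array(), f,
        float(config.t_end), float(config.record_every),
        int(config.seed), physical)
    meta = {
        "engine": "gillespie", "volume": config.volume, "seed": int(config.seed),
        "channel_mode": config.channel_mode, "f": f, "n_events": int(n_events),
        "stalled": bool(stalled), "params": params.to_dict(),
        "signal": signal.as_array().tolist(),
    }
    return Trajectory(times, out, signal, meta, is_counts=True, f=f)
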