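"""Fixed-step RK4 integration of the NF-κB model and the Trajectory container.

The integrator is deliberately plain: classic 4th-order Runge-Kutta with a
fixed step, evaluating the square-wave forcing at sub-stage times and
stepping straight across its discontinuities.  For the default dt = 0.01 min
the edge error is far below the scale of any quantity analysed downstream,
and identical inputs reproduce trajectories bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import _kernels
from .errors import IntegrationDivergedError, InvalidInputError
from .model import STATE_NAMES, ModelParameters, ModelState, TNFSignal, tnf_value

__all__ = ["Trajectory", "integrate_rk4", "DEFAULT_DT", "DEFAULT_RECORD_EVERY", "DEFAULT_TRANSIENT"]

DEFAULT_DT = 0.01
DEFAULT_RECORD_EVERY = 1.0
#: conventional transient to discard before analysing asymptotic behaviour
DEFAULT_TRANSIENT = 1000.0

DEFAULT_INIT = ModelState(Nn=0.0, Im=0.0, I=0.5, IKKa=0.0, IKKi=0.0)


@dataclass
class Trajectory:
    """A sampled time course of the five model species.

    ``states`` holds concentrations (μM) for deterministic runs and integer
    molecule counts for stochastic runs (``is_counts`` set, with ``f`` the
    molecules-per-μM conversion factor).
    """

    times: np.ndarray
    states: np.ndarray
    signal: TNFSignal
    meta: dict[str, Any] = field(default_factory=dict)
    is_counts: bool = False
    f: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states)
        if self.times.ndim != 1 or self.states.shape != (self.times.size, 5):
            raise InvalidInputError("times must be 1-D and states (len(times), 5)")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidInputError("times must be strictly increasing")

    def concentrations(self) -> np.ndarray:
        """States as concentrations (μM), converting counts via f."""
        if self.is_counts:
            return self.states / self.f
        return self.states

    def column(self, name: str) -> np.ndarray:
        """One species' concentration time course by name ('Nn', 'Im', ...)."""
        return self.concentrations()[:, STATE_NAMES.index(name)]

    @property
    def nn(self) -> np.ndarray:
        return self.column("Nn")

    def tnf(self) -> np.ndarray:
        return np.array([tnf_value(t, self.signal) for t in self.times])

    def after(self, t0: float) -> "Trajectory":
        """Sub-trajectory with times >= t0 (transient discard)."""
        mask = self.times >= t0
        return Trajectory(self.times[mask], self.states[mask], self.signal,
                          dict(self.meta), self.is_counts, self.f)

    def __len__(self) -> int:
        return int(self.times.size)


def integrate_rk4(
    init: ModelState | np.ndarray | None = None,
    params: ModelParameters | None = None,
    signal: TNFSignal | None = None,
    t_end: float = 3000.0,
    dt: float = DEFAULT_DT,
    record_every: float = DEFAULT_RECORD_EVERY,
    t0: float = 0.0,
) -> Trajectory:
    """Integrate the model with classic fixed-step RK4.

    Samples are recorded at multiples of ``record_every`` (which must be an
    integer multiple of ``dt``, up to rounding); the initial state is row 0.
    Raises :class:`IntegrationDivergedError` if the state turns non-finite.
    """
    params = params or ModelParameters()
    signal = signal or TNFSignal.constant()
    if init is None:
        init = DEFAULT_INIT
    y0 = init.as_array() if isinstance(init, ModelState) else np.asarray(init, dtype=float)
    if not (dt > 0 and t_end > t0 and record_every >= dt):
        raise InvalidInputError("need dt > 0, t_end > t0 and record_every >= dt")
    n_sub = int(round(record_every / dt))
    dt_eff = record_every / n_sub
    n_rec = int(round((t_end - t0) / record_every))
    states, status, fail_t = _kernels.rk4_kernel(
        y0, params.as_array(), signal.as_array(), t0, n_rec, n_sub, dt_eff)
    if status != 0:
        raise IntegrationDivergedError(fail_t)
    times = t0 + np.arange(n_rec + 1) * record_every
    meta = {"engine": "rk4", "dt": dt_eff, "t0": t0,
            "params": params.to_dict(), "signal": signal.as_array().tolist()}
    return Trajectory(times, states, signal, meta)


def random_initial_states(n: int, params: ModelParameters, seed: int) -> list[ModelState]:
    """Seeded uniform draws inside the admissible box.

    Nn ∈ [0, Ntot]; Im and I over the ranges the attractor actually visits
    (mRNA can accumulate because its decay is slow); IKKa/IKKi scaled so
    their sum stays below IKKtot.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        nn = rng.uniform(0, params.Ntot)
        im = rng.uniform(0, 6.0)
        iprot = rng.uniform(0, 1.5)
        u1, u2 = rng.uniform(0, 1, 2)
        tot = rng.uniform(0, params.IKKtot)
        ikka = tot * u1
        ikki = (tot - ikka) * u2
        out.append(ModelState(nn, im, iprot, ikka, ikki))
    return out
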