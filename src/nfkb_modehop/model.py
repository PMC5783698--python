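"""Core NF-κB negative-feedback model: parameters, state, TNF forcing, and the vector field.

The model tracks five concentrations (all in μM): nuclear NF-κB ``Nn``, IκB
mRNA ``Im``, cytoplasmic IκB protein ``I``, active IKK ``IKKa`` and inactive
IKK ``IKKi``.  TNF enters as a dimensionless multiplicative input: it drives
IKK activation and accelerates IKK recycling through A20.  The negative
feedback loop (NF-κB → IκB mRNA → IκB → nuclear export of NF-κB) produces
spiky limit-cycle oscillations with a free-running period of roughly an hour
and a half, which can be entrained by periodic TNF input.

The five coupled rate equations are::

    dNn/dt   = kNin (Ntot − Nn) KI/(KI + I)  −  kIin I Nn/(KN + Nn)
    dIm/dt   = kt Nn²  −  γm Im
    dI/dt    = ktl Im  −  α IKKa (Ntot − Nn) I/(KI + I)
    dIKKa/dt = ka TNF (IKKtot − IKKa − IKKi)  −  ki IKKa
    dIKKi/dt = ki IKKa  −  kp IKKi kA20/(kA20 + A20·TNF)

Neutral (recycled) IKK is the derived pool ``IKKtot − IKKa − IKKi`` and is
never stored.  Total NF-κB and total IKK are conserved by construction.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidInputError, InvalidStateError

__all__ = [
    "ModelParameters",
    "ModelState",
    "TNFSignal",
    "default_parameters",
    "tnf_value",
    "model_rhs",
    "PARAM_NAMES",
    "STATE_NAMES",
]

PARAM_NAMES = (
    "kNin", "kIin", "kt", "ktl", "KI", "KN", "gamma_m", "alpha",
    "Ntot", "ka", "ki", "kp", "kA20", "IKKtot", "A20",
)

STATE_NAMES = ("Nn", "Im", "I", "IKKa", "IKKi")


@dataclass(frozen=True)
class ModelParameters:
    """The 15 rate/affinity constants of the NF-κB system.

    Units: first-order rates in min⁻¹, the bimolecular constants ``kt`` and
    ``alpha`` in μM⁻¹·min⁻¹, affinities (``KI``, ``KN``, ``kA20``) and total
    pools (``Ntot``, ``IKKtot``, ``A20``) in μM.
    """

    kNin: float = 5.4
    kIin: float = 0.018
    kt: float = 1.03
    ktl: float = 0.24
    KI: float = 0.035
    KN: float = 0.029
    gamma_m: float = 0.018
    alpha: float = 1.05
    Ntot: float = 1.0
    ka: float = 0.24
    ki: float = 0.18
    kp: float = 0.036
    kA20: float = 0.0018
    IKKtot: float = 2.0
    A20: float = 0.0026

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidInputError(f"parameter {name} must be strictly positive, got {v!r}")

    def as_array(self) -> np.ndarray:
        """Parameter vector in the canonical ``PARAM_NAMES`` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=np.float64)

    def replace(self, **kwargs: float) -> "ModelParameters":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParameters":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise InvalidInputError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def dump(self, path: str | Path) -> None:
        """Write as a flat YAML/JSON-compatible key-value file."""
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ModelParameters":
        import yaml  # JSON is a YAML subset, so one loader covers both

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_parameters() -> ModelParameters:
    """The published default parameter set (all 15 values)."""
    return ModelParameters()


@dataclass
class ModelState:
    """Instantaneous concentrations (μM) of the five model species."""

    Nn: float = 0.0
    Im: float = 0.0
    I: float = 0.5
    IKKa: float = 0.0
    IKKi: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.Nn, self.Im, self.I, self.IKKa, self.IKKi], dtype=np.float64)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        return cls(*(float(v) for v in y))

    def validate(self, params: ModelParameters, tol: float = 1e-9) -> None:
        y = self.as_array()
        if not np.all(np.isfinite(y)):
            raise InvalidStateError(f"non-finite state: {self}")
        if np.any(y < -tol):
            raise InvalidStateError(f"negative concentration in state: {self}")
        if self.Nn > params.Ntot + tol:
            raise InvalidStateError(f"Nn = {self.Nn} exceeds Ntot = {params.Ntot}")
        if self.IKKa + self.IKKi > params.IKKtot + tol:
            raise InvalidStateError("IKKa + IKKi exceeds IKKtot")


@dataclass(frozen=True)
class TNFSignal:
    """Square-pulse TNF input.

    The waveform is a symmetric square wave around ``baseline``: during the
    first ``duty`` fraction of each cycle the value is ``baseline + amplitude``
    and during the rest ``max(baseline − amplitude, 0)``.  ``constant_flag``
    (or zero amplitude) degenerates to the constant baseline, the
    free-running reference condition.
    """

    period: float = 90.0
    amplitude: float = 0.0
    baseline: float = 1.0
    duty: float = 0.5
    constant_flag: bool = False

    def __post_init__(self) -> None:
        if not self.constant_flag and not (self.period > 0 and math.isfinite(self.period)):
            raise InvalidInputError(f"period must be > 0, got {self.period!r}")
        if not (self.amplitude >= 0 and math.isfinite(self.amplitude)):
            raise InvalidInputError(f"amplitude must be >= 0, got {self.amplitude!r}")
        if not (0.0 <= self.duty <= 1.0):
            raise InvalidInputError(f"duty must lie in [0, 1], got {self.duty!r}")
        if not (self.baseline >= 0 and math.isfinite(self.baseline)):
            raise InvalidInputError(f"baseline must be >= 0, got {self.baseline!r}")

    @classmethod
    def constant(cls, level: float = 1.0) -> "TNFSignal":
        return cls(period=1.0, amplitude=0.0, baseline=level, constant_flag=True)

    def as_array(self) -> np.ndarray:
        """(period, amplitude, baseline, duty, constant) vector for the kernels."""
        return np.array(
            [self.period if not self.constant_flag else 1.0,
             self.amplitude, self.baseline, self.duty,
             1.0 if self.constant_flag else 0.0],
            dtype=np.float64,
        )


def tnf_value(t: float, signal: TNFSignal) -> float:
    """TNF level at time ``t`` (min)."""
    if not math.isfinite(t):
        raise InvalidInputError(f"time must be finite, got {t!r}")
    if signal.constant_flag or signal.amplitude == 0.0:
        return signal.baseline
    phase = t % signal.period
    if phase < signal.duty * signal.period:
        return signal.baseline + signal.amplitude
    return max(signal.baseline - signal.amplitude, 0.0)


def model_rhs(
    state: ModelState | np.ndarray,
    t: float,
    params: ModelParameters,
    signal: TNFSignal,
) -> np.ndarray:
    """Time derivatives (μM·min⁻¹) of the five species at time ``t``."""
    y = state.as_array() if isinstance(state, ModelState) else np.asarray(state, dtype=float)
    tnf = tnf_value(t, signal)
    return rhs_concentrations(y, tnf, params.as_array())


def rhs_concentrations(y: np.ndarray, tnf: float, p: np.ndarray) -> np.ndarray:
    """Vector field at fixed TNF level; ``p`` in ``PARAM_NAMES`` order."""
    kNin, kIin, kt, ktl, KI, KN, gm, alpha, Ntot, ka, ki, kp, kA20, IKKtot, A20 = p
    Nn, Im, I, IKKa, IKKi = y
    dNn = kNin * (Ntot - Nn) * KI / (KI + I) - kIin * I * Nn / (KN + Nn)
    dIm = kt * Nn * Nn - gm * Im
    dI = ktl * Im - alpha * IKKa * (Ntot - Nn) * I / (KI + I)
    dIKKa = ka * tnf * (IKKtot - IKKa - IKKi) - ki * IKKa
    dIKKi = ki * IKKa - kp * IKKi * kA20 / (kA20 + A20 * tnf)
    return np.array([dNn, dIm, dI, dIKKa, dIKKi])
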