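"""Two-gene frequency-multiplexing model downstream of NF-κB.

Each gene is transcribed at a Hill-function rate of the nuclear NF-κB level
and translated with first-order kinetics::

    dm/dt = γ N^h / (K^h + N^h) − δ m
    dP/dt = Γ m − Δ P

Gene 1 (h = 2) and gene 2 (h = 4) share K = 1 but differ in cooperativity,
so gene 1 responds at lower NF-κB levels while gene 2 needs excursions above
K.  Distinct entrainment modes produce oscillations with different amplitudes
(lower frequency ⇒ larger NF-κB excursions), so mode-hopping switches the
low-affinity-behaving gene 2 between low and high production while gene 1
stays on — frequency multiplexing of downstream expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .deterministic import Trajectory
from .errors import InvalidInputError

__all__ = ["GeneParams", "GeneState", "hill_steady_state", "simulate_genes",
           "default_genes", "GENE1", "GENE2"]


@dataclass(frozen=True)
class GeneParams:
    """Hill-kinetics parameters of one NF-κB target gene.

    K: half-saturation (#molecules); h: Hill coefficient; gamma/delta: mRNA
    production (#molecules·min⁻¹) and decay (min⁻¹); Gamma/Delta: protein
    production and decay (min⁻¹).
    """

    K: float = 1.0
    h: float = 2.0
    gamma: float = 4.0
    delta: float = 2.0
    Gamma: float = 2.0
    Delta: float = 0.3
    name: str = "gene"

    def __post_init__(self) -> None:
        for fname in ("K", "h", "gamma", "delta", "Gamma", "Delta"):
            if not getattr(self, fname) > 0:
                raise InvalidInputError(f"{fname} must be > 0")
        if self.h < 1:
            raise InvalidInputError("Hill coefficient must be >= 1")


GENE1 = GeneParams(K=1.0, h=2.0, name="gene1")
GENE2 = GeneParams(K=1.0, h=4.0, name="gene2")


def default_genes() -> list[GeneParams]:
    """The published two-gene set: equal K, cooperativity 2 vs 4."""
    return [GENE1, GENE2]


@dataclass
class GeneState:
    """mRNA and protein copy numbers of one gene."""

    m: float = 0.0
    P: float = 0.0


def hill_steady_state(N: float, gene: GeneParams) -> tuple[float, float]:
    """Steady-state (m, P) under a constant NF-κB level N.

    m_ss = (γ/δ)·N^h/(K^h + N^h), P_ss = (Γ/Δ)·m_ss.
    """
    if N < 0:
        raise InvalidInputError("N must be >= 0")
    hill = 0.0 if N == 0 else N ** gene.h / (gene.K ** gene.h + N ** gene.h)
    m_ss = gene.gamma / gene.delta * hill
    return m_ss, gene.Gamma / gene.Delta * m_ss


def simulate_genes(
    nfkb_trace: Trajectory | tuple[np.ndarray, np.ndarray],
    genes: list[GeneParams] | None = None,
    scaling: float | None = None,
    dt: float = 0.01,
    init: GeneState | None = None,
) -> pd.DataFrame:
    """Integrate the gene pairs driven by an NF-κB time course.

    ``scaling`` converts the trace (μM for simulated trajectories) to the
    gene model's #molecules scale.  By default the trace is normalised so
    its *maximum* over the input window equals 1.0 (= K): oscillation peaks
    then sit at the Hill half-saturation point, the regime in which the two
    promoters discriminate between entrainment modes (a higher-amplitude
    mode pushes its peaks up the steep part of the low-affinity gene's
    response, a lower-amplitude one does not).  When comparing several
    modes of one cell, pass one shared explicit factor — e.g. K over the
    largest mode's maximum — so the comparison preserves amplitude
    differences.  Returns a frame with columns time, N and m_i/P_i per gene.
    """
    genes = genes if genes is not None else default_genes()
    if isinstance(nfkb_trace, Trajectory):
        t, N = nfkb_trace.times, nfkb_trace.nn
    else:
        t, N = (np.asarray(x, dtype=float) for x in nfkb_trace)
    if t.size < 2:
        raise InvalidInputError("NF-κB trace must have at least 2 samples")
    if scaling is None:
        peak = float(np.max(N))
        if peak <= 0:
            raise InvalidInputError("cannot auto-scale a nonpositive trace")
        scaling = 1.0 / peak
    if not scaling > 0:
        raise InvalidInputError("scaling must be > 0")
    init = init or GeneState()
    n_steps = int(np.floor((t[-1] - t[0]) / dt))
    grid_half = t[0] + np.arange(2 * n_steps + 1) * (dt / 2.0)
    N_half = np.interp(grid_half, t, N) * scaling
    out = {"time": t[0] + np.arange(n_steps + 1) * dt}
    out["N"] = N_half[::2]
    for g in genes:
        m, P = _kernels.gene_kernel(N_half, float(dt), g.K, g.h, g.gamma,
                                    g.delta, g.Gamma, g.Delta,
                                    float(init.m), float(init.P))
        out[f"m_{g.name}"] = m
        out[f"P_{g.name}"] = P
    return pd.DataFrame(out)
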