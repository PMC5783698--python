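"""Arnold tongue mapping, multistability detection, and chaos diagnostics.

A driven oscillator locks to the forcing over wedge-shaped regions of the
(forcing period, forcing amplitude) plane — the Arnold tongues.  Each grid
cell is classified by integrating the model to its attractor and reading the
asymptotic ratio r = NF-κB period / TNF period off the inter-peak intervals.
Overlapping tongues show up as multistability (different locked ratios from
different initial conditions), and at large forcing amplitude the overlaps
give way to chaos, diagnosed here by the largest Lyapunov exponent (Benettin
two-trajectory method) and by period-doubling of the peak-height sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from . import _kernels
from .analysis import (DEFAULT_RATIOS, DEFAULT_TOLERANCE, PeakSeries,
                       classify_modes, detect_peaks)
from .deterministic import DEFAULT_INIT, integrate_rk4, random_initial_states
from .errors import InsufficientDataError, InvalidInputError
from .model import ModelParameters, ModelState, TNFSignal

__all__ = [
    "ScanSettings", "ArnoldTongueMap", "asymptotic_ratio", "tongue_scan",
    "multistability_scan", "lyapunov_benettin", "detect_period_doubling",
]


@dataclass(frozen=True)
class ScanSettings:
    """Settings shared by the tongue-scan operations.

    The NF-κB limit cycles attract very slowly (amplitude relaxation over
    thousands of minutes), so the default transient is generous; the fast
    compiled integrator makes this cheap.  ``lock_tol`` bounds the relative
    deviation of the measured rotation number (mean inter-peak interval /
    forcing period) from its rational candidate — true frequency locking
    means the rotation number *equals* the rational, so a drifting
    quasi-periodic orbit near an allowed ratio is rejected.
    ``max_denominator`` limits the order of rational lockings considered
    (higher-order tongues such as 7:4 are real but increasingly narrow).
    """

    transient: float = 10000.0
    horizon_cycles: int = 40
    dt: float = 0.01
    record_every: float = 1.0
    agreement: float = 0.90
    allowed_ratios: tuple = DEFAULT_RATIOS
    tolerance: float = DEFAULT_TOLERANCE
    lock_tol: float = 0.02
    max_denominator: int = 4
    min_separation: float = 20.0
    smooth_window: int = 1  # deterministic traces need no smoothing

    def __post_init__(self) -> None:
        if self.horizon_cycles < 10:
            raise InvalidInputError("horizon must be at least 10 forcing cycles")


DEFAULT_SETTINGS = ScanSettings()


@dataclass
class ArnoldTongueMap:
    """Grid over (forcing period, amplitude) with per-cell lock results."""

    period_grid: np.ndarray
    amplitude_grid: np.ndarray
    ratio: np.ndarray          # object array of Fraction or None
    reason: np.ndarray         # short text for unlocked cells
    multistable: np.ndarray | None = None
    lyapunov: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, T in enumerate(self.period_grid):
            for j, A in enumerate(self.amplitude_grid):
                r = self.ratio[i, j]
                rows.append({
                    "period": T, "amplitude": A,
                    "ratio": str(r) if r is not None else "unlocked",
                    "ratio_value": float(r) if r is not None else np.nan,
                    "reason": self.reason[i, j],
                    "multistable": (bool(self.multistable[i, j])
                                    if self.multistable is not None else np.nan),
                    "lyapunov": (float(self.lyapunov[i, j])
                                 if self.lyapunov is not None else np.nan),
                })
        return pd.DataFrame(rows)


def _peaks_after_transient(params, signal, init, settings: ScanSettings) -> PeakSeries:
    t_end = settings.transient + settings.horizon_cycles * signal.period
    traj = integrate_rk4(init, params, signal, t_end=t_end, dt=settings.dt,
                         record_every=settings.record_every)
    tail = traj.after(settings.transient)
    return detect_peaks(tail.times, tail.nn,
                        smooth_window=settings.smooth_window,
                        min_separation=settings.min_separation)


def asymptotic_ratio(
    params: ModelParameters,
    signal: TNFSignal,
    init: ModelState | None = None,
    settings: ScanSettings = DEFAULT_SETTINGS,
) -> tuple[Fraction | None, str]:
    """Locked period ratio of the attractor reached from ``init``.

    Integrates through the transient, detects peaks over the horizon and
    requires at least ``settings.agreement`` of the intervals to carry one
    identical label; otherwise (or with no/too few peaks) the cell is
    unlocked, with a short reason string.
    """
    init = init or DEFAULT_INIT
    peaks = _peaks_after_transient(params, signal, init, settings)
    if len(peaks) < 3:
        return None, "no oscillation"
    intervals = peaks.intervals
    # rotation number: a locked orbit has mean interval exactly r·T, while a
    # quasi-periodic orbit drifts near the free-running period instead
    rho = float(np.mean(intervals)) / signal.period
    cand = Fraction(rho).limit_denominator(settings.max_denominator)
    if cand == 0 or abs(rho / float(cand) - 1.0) > settings.lock_tol:
        return None, "rotation number not locked"
    # the locked pattern may cycle through unequal sub-intervals (e.g. the
    # 87/93-min alternation inside a 1:2 locking); every interval must still
    # classify to the same candidate ratio
    allowed = tuple(dict.fromkeys(tuple(settings.allowed_ratios) + (cand,)))
    modes = classify_modes(intervals, signal.period, allowed, settings.tolerance)
    agree = sum(1 for l in modes.labels if l == cand) / len(modes)
    if agree < settings.agreement:
        return None, "no dominant mode"
    return cand, "locked"


def tongue_scan(
    period_grid,
    amplitude_grid,
    params: ModelParameters | None = None,
    settings: ScanSettings = DEFAULT_SETTINGS,
    init: ModelState | None = None,
) -> ArnoldTongueMap:
    """Classify every grid cell independently (order-independent by design).

    Per-cell failures become unlocked-with-reason entries; the scan never
    aborts.
    """
    params = params or ModelParameters()
    period_grid = np.asarray(period_grid, dtype=float)
    amplitude_grid = np.asarray(amplitude_grid, dtype=float)
    if period_grid.size == 0 or amplitude_grid.size == 0:
        raise InvalidInputError("grids must be nonempty")
    ratio = np.empty((period_grid.size, amplitude_grid.size), dtype=object)
    reason = np.empty_like(ratio)
    for i, T in enumerate(period_grid):
        for j, A in enumerate(amplitude_grid):
            try:
                sig = TNFSignal(period=float(T), amplitude=float(A))
                r, why = asymptotic_ratio(params, sig, init, settings)
            except Exception as exc:  # pragma: no cover - defensive
                r, why = None, f"error: {exc}"
            ratio[i, j] = r
            reason[i, j] = why
    return ArnoldTongueMap(period_grid, amplitude_grid, ratio, reason)


def multistability_scan(
    signal: TNFSignal,
    params: ModelParameters | None = None,
    n_init: int = 20,
    seed: int = 0,
    settings: ScanSettings = DEFAULT_SETTINGS,
    return_inits: bool = False,
):
    """Distinct locked ratios reached from seeded random initial conditions.

    More than one distinct ratio means overlapping Arnold tongues: several
    limit cycles coexist and the basin of attraction decides which one a
    trajectory settles into.
    """
    if n_init < 1:
        raise InvalidInputError("n_init must be >= 1")
    params = params or ModelParameters()
    found: set[Fraction] = set()
    per_init = []
    for st in random_initial_states(n_init, params, seed):
        r, _ = asymptotic_ratio(params, signal, st, settings)
        per_init.append((st, r))
        if r is not None:
            found.add(r)
    if return_inits:
        return found, per_init
    return found


def lyapunov_benettin(
    params: ModelParameters,
    signal: TNFSignal,
    init: ModelState | None = None,
    delta0: float = 1.0 / 602.2,
    tau: float = 10.0,
    t_total: float = 4000.0,
    dt: float = 0.01,
    transient: float = 1000.0,
) -> tuple[float, float]:
    """Largest Lyapunov exponent (min⁻¹) by the two-trajectory Benettin method.

    A reference and a copy perturbed by ``delta0`` (default: one molecule at
    the 10⁻¹⁵ L reference volume, ≈1/602 μM) are integrated side by side;
    every ``tau`` minutes the separation is renormalised and its ln-growth
    accumulated.  Returns (exponent, standard error over renormalisation
    blocks); positive exponents beyond the error bar indicate chaos.
    """
    if not delta0 > 0:
        raise InvalidInputError("delta0 must be > 0 (degenerate perturbation)")
    if not t_total > 10 * tau:
        raise InvalidInputError("t_total must be much larger than tau")
    init = init or DEFAULT_INIT
    n_blocks = int(round(t_total / tau))
    logs = _kernels.benettin_kernel(init.as_array(), params.as_array(),
                                    signal.as_array(), float(delta0),
                                    float(tau), n_blocks, float(dt),
                                    float(transient))
    lam = float(np.mean(logs) / tau)
    se = float(np.std(logs, ddof=1) / np.sqrt(len(logs)) / tau)
    return lam, se


def detect_period_doubling(peaks: PeakSeries, rel_tol: float = 0.05):
    """Classify the peak-height sequence as period 1, 2, 4 or aperiodic.

    Returns the smallest k in {1, 2, 4} such that heights repeat with period
    k within relative tolerance, else the string 'aperiodic'.
    """
    h = np.asarray(peaks.peak_heights, dtype=float)
    if h.size < 8:
        raise InsufficientDataError(f"need at least 8 peaks, got {h.size}")
    for k in (1, 2, 4):
        diffs = np.abs(h[k:] - h[:-k])
        ref = np.abs(h[:-k])
        if np.all(diffs <= rel_tol * np.maximum(ref, 1e-300)):
            # genuine period k: for k > 1 the subcycle values must differ
            if k == 1:
                return 1
            sub_ok = False
            for off in range(1, k):
                if np.any(np.abs(h[off:] - h[:-off]) > rel_tol * np.abs(h[:-off])):
                    sub_ok = True
            if sub_ok:
                return k
            return 1
    return "aperiodic"
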