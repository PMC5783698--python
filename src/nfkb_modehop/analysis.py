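"""Trace analysis: peak detection, entrainment-mode classification, hopping statistics.

Works on any NF-κB time course — deterministic or stochastic simulation
output, synthetic traces, or measured single-cell tables (time vs. nuclear
intensity).  The pipeline is: smooth → detect peaks (10%-of-maximum height
filter, minimum separation) → inter-peak intervals → snap each interval to
the nearest allowed period ratio r = NF-κB period / TNF period → count
occupancy, dwell times and mode-hopping transitions.

Mode labels are exact :class:`fractions.Fraction` values; an interval whose
period is not within the relative tolerance of any allowed ratio is labelled
unentrained (``None``).  Note the two conventions in circulation: the ratio
r = 1/2 here (NF-κB period half the TNF period) is the "1:2 input:oscillator"
locking; :func:`ratio_label` renders both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "PeakSeries", "ModeSequence", "detect_peaks", "classify_modes",
    "mode_statistics", "period_views", "transition_heatmap",
    "DEFAULT_RATIOS", "ratio_label", "smooth",
]

#: default allowed period ratios r = NF-κB period / TNF period
DEFAULT_RATIOS = (Fraction(1, 3), Fraction(1, 2), Fraction(1), Fraction(2),
                  Fraction(3), Fraction(4))

DEFAULT_SMOOTH_WINDOW = 5
DEFAULT_THRESHOLD_FRAC = 0.10
DEFAULT_MIN_SEPARATION = 20.0
DEFAULT_TOLERANCE = 0.20


def ratio_label(ratio: Fraction | None) -> str:
    """Human-readable label: period ratio plus input:oscillator notation."""
    if ratio is None:
        return "unentrained"
    return f"{ratio} ({ratio.denominator}:{ratio.numerator} input:oscillator)"


@dataclass
class PeakSeries:
    """Detected peaks of one trace: times, heights, inter-peak intervals."""

    peak_times: np.ndarray
    peak_heights: np.ndarray

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.peak_heights = np.asarray(self.peak_heights, dtype=float)
        if self.peak_times.size > 1 and not np.all(np.diff(self.peak_times) > 0):
            raise InvalidInputError("peak times must be strictly increasing")

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.peak_times)

    def __len__(self) -> int:
        return int(self.peak_times.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"peak_time": self.peak_times, "peak_height": self.peak_heights})


@dataclass
class ModeSequence:
    """Per-interval entrainment labels (Fraction ratio or None = unentrained)."""

    labels: list[Fraction | None]
    tnf_period: float
    allowed_ratios: tuple[Fraction, ...] = DEFAULT_RATIOS
    tolerance: float = DEFAULT_TOLERANCE
    intervals: np.ndarray = field(default_factory=lambda: np.array([]))

    def __len__(self) -> int:
        return len(self.labels)

    def entrained(self) -> list[Fraction]:
        return [l for l in self.labels if l is not None]

    def distinct_modes(self) -> set[Fraction]:
        return set(self.entrained())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "interval": np.arange(len(self.labels)),
            "period": self.intervals if len(self.intervals) == len(self.labels) else np.nan,
            "ratio": [str(l) if l is not None else "unentrained" for l in self.labels],
        })


def smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    values = np.asarray(values, dtype=float)
    if window <= 1:
        return values.copy()
    kernel = np.ones(window)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def detect_peaks(
    times: Sequence[float],
    values: Sequence[float],
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> PeakSeries:
    """Smooth, find strict local maxima, filter by height and separation.

    Peaks below ``threshold_frac`` of the smoothed trace's maximum are
    discarded; peaks closer than ``min_separation`` keep only the higher one.
    A constant trace yields an empty series.  The threshold is relative, so
    the result is invariant to affine rescaling of the trace.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise InvalidInputError("times and values must be 1-D and equal length")
    if t.size < 3:
        raise InvalidInputError("need at least 3 samples")
    if not np.all(np.diff(t) > 0):
        raise InvalidInputError("times must be strictly increasing")
    sm = smooth(v, smooth_window)
    lo, hi = sm.min(), sm.max()
    if hi <= lo:
        return PeakSeries(np.array([]), np.array([]))
    dt = np.median(np.diff(t))
    distance = max(1, int(round(min_separation / dt)))
    # height threshold relative to the smoothed maximum, measured from the
    # trace floor so that traces riding on a baseline behave like the raw
    # intensity convention (10% of maximum intensity)
    height = lo + threshold_frac * (hi - lo)
    idx, _ = find_peaks(sm, height=height, distance=distance)
    return PeakSeries(t[idx], sm[idx])


def classify_modes(
    intervals: Sequence[float],
    tnf_period: float,
    allowed_ratios: Sequence[Fraction | float] = DEFAULT_RATIOS,
    tolerance: float = DEFAULT_TOLERANCE,
) -> ModeSequence:
    """Snap each inter-peak interval to the nearest allowed period ratio.

    Interval p maps to the allowed ratio r minimising |p/T − r|/r; if even
    the nearest ratio is off by more than ``tolerance`` (relative), the
    interval is unentrained.  Scale-invariant: classify(c·p, c·T) ≡
    classify(p, T).
    """
    if not tnf_period > 0:
        raise InvalidInputError("tnf_period must be > 0")
    if not 0 < tolerance < 0.5:
        raise InvalidInputError("tolerance must lie in (0, 0.5)")
    ratios = tuple(r if isinstance(r, Fraction) else Fraction(r).limit_denominator(100)
                   for r in allowed_ratios)
    if not ratios:
        raise InvalidInputError("allowed_ratios must be nonempty")
    intervals = np.asarray(list(intervals), dtype=float)
    labels: list[Fraction | None] = []
    for p in intervals:
        x = p / tnf_period
        best, best_err = None, np.inf
        for r in ratios:
            err = abs(x - float(r)) / float(r)
            if err < best_err:
                best, best_err = r, err
        labels.append(best if best_err <= tolerance else None)
    return ModeSequence(labels, tnf_period, ratios, tolerance, intervals)


def mode_statistics(modes: ModeSequence) -> dict:
    """Occupancy, transition rate and dwell-length distributions.

    Occupancy is the fraction of intervals per label (unentrained included),
    summing to 1.  A transition is a label change between two *adjacent*
    entrained intervals; unentrained intervals break dwell runs but are not
    themselves counted as transitions.  The rate is normalised per 1000
    oscillations (intervals).
    """
    if len(modes) < 1:
        raise InsufficientDataError("need at least one labeled interval")
    labels = modes.labels
    n = len(labels)
    occupancy: dict = {}
    for l in labels:
        key = l if l is not None else "unentrained"
        occupancy[key] = occupancy.get(key, 0) + 1
    occupancy = {k: c / n for k, c in occupancy.items()}
    transitions = sum(
        1 for a, b in zip(labels, labels[1:])
        if a is not None and b is not None and a != b
    )
    dwell: dict[Fraction, list[int]] = {}
    run_label, run_len = None, 0
    for l in labels + [None]:  # sentinel flushes the last run
        if l is not None and l == run_label:
            run_len += 1
            continue
        if run_label is not None and run_len > 0:
            dwell.setdefault(run_label, []).append(run_len)
        run_label, run_len = l, (1 if l is not None else 0)
    return {
        "occupancy": occupancy,
        "n_intervals": n,
        "n_transitions": transitions,
        "transitions_per_1000": 1000.0 * transitions / n,
        "dwell_lengths": dwell,
    }


def period_views(
    intervals: Sequence[float],
    tnf_period: float,
    bin_width: float = 5.0,
) -> dict:
    """Histogram of inter-peak periods and the lag-1 return map.

    The histogram bins are aligned so that integer multiples of the TNF
    period fall at bin centers; ``lag1_pairs`` lists (p_k, p_{k+1}) in order,
    the period-to-period correlation view.
    """
    p = np.asarray(list(intervals), dtype=float)
    if p.size == 0:
        return {"hist_counts": np.array([]), "hist_edges": np.array([]), "lag1_pairs": np.empty((0, 2))}
    lo = max(0.0, p.min() - bin_width)
    hi = p.max() + bin_width
    edges = np.arange(lo - bin_width / 2, hi + bin_width, bin_width)
    counts, edges = np.histogram(p, bins=edges)
    pairs = np.column_stack([p[:-1], p[1:]]) if p.size >= 2 else np.empty((0, 2))
    return {"hist_counts": counts, "hist_edges": edges, "lag1_pairs": pairs,
            "tnf_period": tnf_period}


def fraction_near_integer_multiple(intervals: Sequence[float], tnf_period: float,
                                   rel_tol: float = 0.15) -> float:
    """Fraction of intervals within rel_tol of some integer multiple of T."""
    p = np.asarray(list(intervals), dtype=float)
    if p.size == 0:
        return 0.0
    mult = np.maximum(1, np.rint(p / tnf_period))
    return float(np.mean(np.abs(p - mult * tnf_period) <= rel_tol * mult * tnf_period))


def transition_heatmap(modes: ModeSequence) -> pd.DataFrame:
    """Conditional next-mode probabilities P(next | current).

    Built from adjacent pairs of entrained intervals; rows are indexed by the
    observed current labels and each row sums to 1 over observed successors.
    """
    pairs = [(a, b) for a, b in zip(modes.labels, modes.labels[1:])
             if a is not None and b is not None]
    if not pairs:
        raise InsufficientDataError("need at least 2 adjacent entrained intervals")
    states = sorted({s for pair in pairs for s in pair})
    counts = pd.DataFrame(0.0, index=[str(s) for s in states], columns=[str(s) for s in states])
    for a, b in pairs:
        counts.loc[str(a), str(b)] += 1
    row_sums = counts.sum(axis=1)
    probs = counts.loc[row_sums > 0].div(row_sums[row_sums > 0], axis=0)
    return probs
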