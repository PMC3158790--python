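"""Threshold flip-flop analysis of paired activity traces.

A slowly varying neuronal activity trace (e.g. SCN multi-unit firing,
expressed in % of its mean NREM level) is compared against a threshold
curve: the instants at which the activity crosses the threshold, upward or
downward, are the candidate switching commands of a two-state (flip-flop)
controller.  These crossing instants are then scored for temporal
alignment against the state-transition instants visible in a second trace
(e.g. the towards/away turning points of slow-wave activity), with the
timing precision limited to about half a bin width by the binning of both
traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fitting import alternating_extrema, smooth3

__all__ = [
    "ActivityTrace",
    "ThresholdCurve",
    "CrossingEvent",
    "StateTransition",
    "AlignmentReport",
    "bin_trace",
    "detect_crossings",
    "detect_state_transitions",
    "align_events",
    "estimate_threshold",
]


@dataclass(frozen=True)
class ActivityTrace:
    """Uniformly binned activity values (% of mean NREM activity)."""

    times: np.ndarray          # bin start times, seconds
    values: np.ndarray         # NaN where the bin is empty
    bin_width: float = 60.0    # seconds (the mean of 6 10-s epochs)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.shape != values.shape:
            raise ValueError("times and values must have equal length")
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")
        if times.size >= 2 and not np.allclose(np.diff(times), self.bin_width):
            raise ValueError("bins must be uniform with the stated width")

    @property
    def centers(self) -> np.ndarray:
        return self.times + self.bin_width / 2.0


@dataclass(frozen=True)
class ThresholdCurve:
    """Threshold value per bin (constant or slowly varying)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @classmethod
    def constant(cls, level: float, n_bins: int) -> "ThresholdCurve":
        return cls(np.full(n_bins, float(level)))


@dataclass(frozen=True)
class CrossingEvent:
    time: float
    direction: str  # "up" or "down"


@dataclass(frozen=True)
class StateTransition:
    time: float
    kind: str  # "away-start" (activity peak) or "towards-start" (trough)


@dataclass(frozen=True)
class AlignmentReport:
    """One-to-one pairing of crossings with reference transitions."""

    matched: int
    total: int
    tolerance: float
    pairs: tuple[tuple[float, float], ...]  # (crossing time, transition time)

    def __post_init__(self) -> None:
        if self.matched > self.total:
            raise ValueError("matched cannot exceed total")

    @property
    def rate(self) -> float | None:
        """Match rate in percent, or None when there is nothing to match."""
        if self.total == 0:
            return None
        return 100.0 * self.matched / self.total

    def to_dict(self) -> dict:
        return {"matched": self.matched, "total": self.total,
                "tolerance_s": self.tolerance, "rate_pct": self.rate,
                "pairs": [list(p) for p in self.pairs]}


def bin_trace(times: Sequence[float], values: Sequence[float],
              bin_width: float = 60.0) -> ActivityTrace:
    """Average a sampled series into uniform bins starting at the first sample.

    Empty bins are missing (NaN).  Note the resolution limitation this
    introduces: a sharp peak about one bin wide whose center falls on a bin
    boundary is split between the neighboring bins, each receiving roughly
    half its amplitude — so the binned trace may fail to reach a threshold
    that the unbinned signal crosses.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0:
        raise ValueError("empty input series")
    if np.any(np.diff(times) < 0):
        raise ValueError("sample times must be sorted")
    t0 = times[0]
    idx = ((times - t0) / bin_width).astype(int)
    n_bins = int(idx.max()) + 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    valid = ~np.isnan(values)
    np.add.at(sums, idx[valid], values[valid])
    np.add.at(counts, idx[valid], 1.0)
    out = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    starts = t0 + np.arange(n_bins) * bin_width
    return ActivityTrace(times=starts, values=out, bin_width=bin_width)


def detect_crossings(trace: ActivityTrace,
                     threshold: ThresholdCurve) -> list[CrossingEvent]:
    """Threshold-crossing instants of a binned trace.

    An event occurs at each sign change of (value - threshold) between
    consecutive non-missing bins; its time is found by linear interpolation
    between the two bin centers.  The effective timing precision is about
    half a bin width.  Consecutive events alternate in direction by
    construction (exact threshold touches carry no sign).
    """
    if threshold.values.shape != trace.values.shape:
        raise ValueError("threshold grid must match the trace grid")
    diff = trace.values - threshold.values
    centers = trace.centers
    idx = np.flatnonzero(~np.isnan(diff))
    events: list[CrossingEvent] = []
    last_sign = 0.0
    last_i: int | None = None
    for i in idx:
        sign = np.sign(diff[i])
        if sign == 0:
            continue
        if last_sign != 0 and sign != last_sign:
            a, b = last_i, i
            frac = diff[a] / (diff[a] - diff[b])
            t = centers[a] + frac * (centers[b] - centers[a])
            events.append(CrossingEvent(time=float(t),
                                        direction="up" if sign > 0 else "down"))
        last_sign, last_i = sign, i
    return events


def detect_state_transitions(trace: ActivityTrace,
                             rel_prominence: float = 0.1) -> list[StateTransition]:
    """Towards/away turning points of a slow-wave-activity trace.

    The trace is smoothed with a three-point moving average and its
    alternating peaks and troughs located: a peak marks the start of an
    *away* interval (activity about to fall), a trough the start of a
    *towards* interval.  Extrema whose prominence is below
    ``rel_prominence`` times the trace range are treated as noise wiggles
    and ignored.
    """
    from scipy.signal import find_peaks

    if trace.values.size < 5:
        raise ValueError("need at least 5 bins")
    smoothed = smooth3(trace.values)
    finite = smoothed[~np.isnan(smoothed)]
    span = float(finite.max() - finite.min())
    if span == 0:
        return []
    prominence = rel_prominence * span
    filled = np.where(np.isnan(smoothed), np.nanmean(smoothed), smoothed)
    peaks, _ = find_peaks(filled, prominence=prominence)
    troughs, _ = find_peaks(-filled, prominence=prominence)
    raw = sorted([(int(i), "max") for i in peaks]
                 + [(int(i), "min") for i in troughs])
    # enforce strict alternation, keeping the more extreme of same-kind runs
    extrema: list[tuple[int, str]] = []
    for i, kind in raw:
        if extrema and extrema[-1][1] == kind:
            j, _ = extrema[-1]
            better = filled[i] > filled[j] if kind == "max" else filled[i] < filled[j]
            if better:
                extrema[-1] = (i, kind)
        else:
            extrema.append((i, kind))
    centers = trace.centers
    return [StateTransition(time=float(centers[i]),
                            kind="away-start" if kind == "max" else "towards-start")
            for i, kind in extrema]


def align_events(crossings: Sequence[CrossingEvent | float],
                 transitions: Sequence[StateTransition | float],
                 tolerance: float) -> AlignmentReport:
    """Greedy nearest-first one-to-one matching of crossings to transitions.

    Candidate pairs within ``tolerance`` are taken in order of ascending
    time difference; each crossing and each reference transition is used at
    most once.  The report counts matched reference transitions.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    ct = [e.time if isinstance(e, CrossingEvent) else float(e) for e in crossings]
    tt = [e.time if isinstance(e, StateTransition) else float(e) for e in transitions]
    candidates = sorted(
        ((abs(c - t), i, j) for i, c in enumerate(ct) for j, t in enumerate(tt)
         if abs(c - t) <= tolerance),
        key=lambda item: item[0])
    used_c: set[int] = set()
    used_t: set[int] = set()
    pairs: list[tuple[float, float]] = []
    for _, i, j in candidates:
        if i in used_c or j in used_t:
            continue
        used_c.add(i)
        used_t.add(j)
        pairs.append((ct[i], tt[j]))
    return AlignmentReport(matched=len(pairs), total=len(tt),
                           tolerance=tolerance, pairs=tuple(pairs))


def estimate_threshold(trace: ActivityTrace, lower_q: float = 0.10,
                       upper_q: float = 0.90) -> ThresholdCurve:
    """Heuristic threshold: midpoint of the lower/upper percentile envelopes.

    Mimics drawing two lines enclosing most of the data points and placing
    the threshold about half way between them.  Supplied thresholds should
    be preferred when available.
    """
    values = trace.values[~np.isnan(trace.values)]
    if values.size == 0:
        raise ValueError("trace has no valid bins")
    lo, hi = np.quantile(values, [lower_q, upper_q])
    return ThresholdCurve.constant((lo + hi) / 2.0, trace.values.size)
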