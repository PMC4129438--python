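"""Burst extraction and rhythm statistics.

Works on spike-per-bin histograms from the network simulator or on burst-time
series from the synthetic generator.  The central statistic is the regularity
score RS_n = T_n / mean(T_{n-1} .. T_{n-j}) with window j = 10: the ratio of
the present cycle period to the mean of the ten preceding periods.  RS stays
near 1 for a stable rhythm and exceeds 1 when the rhythm is slowing; cycle-to-
cycle fluctuations of RS indicate irregularity.

Cessation is operationalized by a quiescence rule: the rhythm is quiescent at
a horizon time if no burst occurred within the trailing 120 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BurstSeries",
    "RegularitySeries",
    "detect_bursts",
    "regularity_score",
    "detect_cessation",
    "normalize_amplitude",
]

#: default burst threshold, as a fraction of the 95th-percentile bin count
DEFAULT_THRESHOLD_FRACTION = 0.2
#: default minimum separation between distinct bursts (s)
DEFAULT_MIN_SEPARATION_S = 0.5
#: quiescence window declaring rhythm cessation (s)
QUIESCENCE_S = 120.0


@dataclass
class BurstSeries:
    """Population bursts: peak times (s), peak amplitudes, and the cycle
    periods T_n = successive peak-time differences (s)."""

    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.size != self.amplitudes.size:
            raise ValueError("times and amplitudes must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("burst times must be strictly increasing")

    @property
    def periods(self) -> np.ndarray:
        return np.diff(self.times)

    def __len__(self) -> int:
        return self.times.size


@dataclass
class RegularitySeries:
    """Per-cycle regularity scores; ``index[k]`` is the (0-based) index into the
    period sequence of the cycle scored by ``rs[k]``."""

    rs: np.ndarray
    index: np.ndarray
    window: int = 10

    def max(self) -> float:
        return float(self.rs.max())


def detect_bursts(
    histogram,
    bin_width_s: float = 0.010,
    threshold: float | None = None,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
    t0_s: float = 0.0,
) -> BurstSeries:
    """Extract population bursts from a spikes-per-bin histogram.

    A burst is a contiguous supra-threshold epoch; epochs whose gaps are
    shorter than ``min_separation_s`` are merged.  The default threshold is
    ``threshold_fraction`` of the 95th-percentile bin count (so an all-zero or
    near-silent histogram yields no bursts).  Peak time is the center of the
    maximal bin within the epoch.
    """
    h = np.asarray(histogram, dtype=float)
    if h.ndim != 1:
        raise ValueError("histogram must be 1-D")
    if np.any(h < 0):
        raise ValueError("histogram counts must be non-negative")
    if h.size == 0 or h.max() == 0:
        return BurstSeries(np.empty(0), np.empty(0))
    if threshold is None:
        threshold = threshold_fraction * np.percentile(h, 95)
        if threshold <= 0:
            threshold = 0.5 * h.max()
    above = h > threshold
    if not above.any():
        return BurstSeries(np.empty(0), np.empty(0))

    # contiguous supra-threshold runs
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    starts, stops = edges[::2], edges[1::2]

    # merge runs separated by less than min_separation_s
    min_gap = max(1, int(round(min_separation_s / bin_width_s)))
    merged = [[starts[0], stops[0]]]
    for s, e in zip(starts[1:], stops[1:]):
        if s - merged[-1][1] < min_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    times, amps = [], []
    for s, e in merged:
        k = s + int(np.argmax(h[s:e]))
        times.append(t0_s + (k + 0.5) * bin_width_s)
        amps.append(h[k])
    return BurstSeries(np.array(times), np.array(amps))


def regularity_score(periods, j: int = 10) -> RegularitySeries:
    """Regularity score RS_n = T_n / mean(T_{n-1}..T_{n-j}).

    Defined for every cycle with at least one prior period; during the first
    ``j`` cycles the mean runs over all available priors.  Requires >= 2
    periods, all positive.
    """
    T = np.asarray(periods, dtype=float)
    if T.size < 2:
        raise ValueError("regularity score needs at least 2 cycle periods")
    if np.any(T <= 0):
        raise ValueError("cycle periods must be positive")
    if j < 1:
        raise ValueError("window must be >= 1")
    rs = np.empty(T.size - 1)
    for n in range(1, T.size):
        lo = max(0, n - j)
        rs[n - 1] = T[n] / T[lo:n].mean()
    return RegularitySeries(rs=rs, index=np.arange(1, T.size), window=j)


def detect_cessation(
    burst_times, horizon_s: float, quiescence_s: float = QUIESCENCE_S
) -> tuple[bool, float]:
    """Quiescence rule: the rhythm has ceased at ``horizon_s`` iff no burst
    occurred within the trailing ``quiescence_s`` window.

    Returns ``(quiescent, onset_s)`` where onset is the last burst time (0.0
    for an empty series, i.e. quiescent from the start).
    """
    if quiescence_s <= 0:
        raise ValueError("quiescence window must be positive")
    t = np.asarray(burst_times, dtype=float)
    if t.size == 0:
        return True, 0.0
    last = float(t.max())
    return (horizon_s - last) > quiescence_s, last


def normalize_amplitude(amplitudes, baseline: slice | np.ndarray) -> np.ndarray:
    """Divide an amplitude series by its mean over a baseline (pre-lesion)
    epoch, so the baseline mean maps to 1.0.

    ``baseline`` is a slice or boolean/index array selecting the baseline
    bursts; it must select at least one.
    """
    a = np.asarray(amplitudes, dtype=float)
    base = a[baseline]
    if base.size == 0:
        raise ValueError("baseline window contains no bursts")
    m = base.mean()
    if m == 0:
        raise ValueError("baseline mean amplitude is zero")
    return a / m
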