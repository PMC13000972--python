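"""Windfleck detection in high-frequency PPFD series.

A windfleck is a brief rise in within-canopy irradiance caused by
wind-driven movement of leaves or stems momentarily exposing the sensor to
direct light.  Events are found by turning-point analysis: the moments at
which the rate of change of the 100 s⁻¹ PPFD series crosses zero mark the
switches between decreasing and increasing irradiance, from which the
start, peak and end of each candidate fleck are read off.  Sensor noise
produces many tiny oscillations, so candidate rises whose amplitude is
below either 5 µmol m⁻² s⁻¹ or 5% of the local baseline are pruned
(smallest first, merging their neighbours) until every remaining rise and
fall clears both thresholds.

Per-event metrics: duration (end − start), intensity (peak − baseline,
where the baseline is the PPFD at the start), and the integrated PPFD
increase (area between the trace and the straight line joining start and
end).  Per-series metrics: fleck frequency and mean time between flecks.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import constants

from .series import IrradianceSeries, check_uniform

__all__ = [
    "WindfleckEvent",
    "FleckSummary",
    "ppfd_from_spectrum",
    "find_turning_points",
    "detect_windflecks",
    "integrated_increase",
    "summarize_flecks",
    "split_segments",
]

DEFAULT_REL_THRESHOLD = 0.05
DEFAULT_ABS_THRESHOLD = 5.0  # µmol m⁻² s⁻¹


@dataclass(frozen=True)
class WindfleckEvent:
    """One detected windfleck.

    Times are in seconds on the series clock; ``baseline`` is the PPFD at
    the start turning point; ``intensity`` = peak − baseline in
    µmol m⁻² s⁻¹; ``integrated_increase`` is in µmol m⁻².
    """

    start_time: float
    peak_time: float
    end_time: float
    baseline: float
    peak_ppfd: float
    intensity: float
    duration: float
    integrated_increase: float
    start_index: int = -1
    peak_index: int = -1
    end_index: int = -1


@dataclass(frozen=True)
class FleckSummary:
    """Series-level windfleck statistics."""

    n_events: int
    total_time: float
    frequency: float          # events s⁻¹
    frequency_per_100s: float
    mean_time_between: float  # s; NaN when fewer than 2 events


def ppfd_from_spectrum(
    wavelengths_nm: np.ndarray, spectral_irradiance: np.ndarray
) -> float:
    """Convert spectral irradiance to PPFD.

    PPFD = 10⁶ · ∫₄₀₀⁷⁰⁰ E(λ) λ / (h c N_A) dλ with E in W m⁻² nm⁻¹ and λ
    in m inside the integrand; trapezoidal quadrature on the native grid,
    with the 400 and 700 nm endpoints interpolated if not on the grid.

    Returns PPFD in µmol m⁻² s⁻¹.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    e = np.asarray(spectral_irradiance, dtype=float)
    if wl.ndim != 1 or wl.shape != e.shape:
        raise ValueError("wavelengths and irradiance must be equal-length 1-D arrays")
    if wl.size < 2 or np.any(np.diff(wl) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    if wl[0] > 400.0 or wl[-1] < 700.0:
        raise ValueError("wavelength grid must cover 400–700 nm")
    lo, hi = 400.0, 700.0
    inside = (wl >= lo) & (wl <= hi)
    wl_in = wl[inside]
    e_in = e[inside]
    if wl_in.size == 0 or wl_in[0] > lo:
        wl_in = np.insert(wl_in, 0, lo)
        e_in = np.insert(e_in, 0, np.interp(lo, wl, e))
    if wl_in[-1] < hi:
        wl_in = np.append(wl_in, hi)
        e_in = np.append(e_in, np.interp(hi, wl, e))
    integrand = e_in * (wl_in * 1e-9)  # W m⁻² nm⁻¹ · m
    photons = np.trapezoid(integrand, wl_in)  # J-normalised, per nm grid
    mol = photons / (constants.h * constants.c * constants.N_A)
    return float(mol * 1e6)


# ---------------------------------------------------------------------------
# turning points and extrema runs

def _value_runs(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compress runs of equal consecutive values.

    Returns (first_index, last_index, value) per run.
    """
    v = np.asarray(values, dtype=float)
    change = np.flatnonzero(np.diff(v) != 0)
    firsts = np.concatenate(([0], change + 1))
    lasts = np.concatenate((change, [v.size - 1]))
    return firsts, lasts, v[firsts]


def find_turning_points(series: IrradianceSeries) -> tuple[np.ndarray, np.ndarray]:
    """Interior indices where the first difference changes sign.

    Plateaus (runs of zero difference) contribute a single turning point at
    the first index of the run.  Returns ``(indices, kinds)`` where kinds is
    an array of +1 (maximum) / −1 (minimum), strictly alternating.
    """
    v = series.values
    if v.size < 3:
        raise ValueError("series must have at least 3 samples")
    firsts, _lasts, rv = _value_runs(v)
    if rv.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    slope = np.sign(np.diff(rv))
    idx, kind = [], []
    for j in range(1, rv.size - 1):
        if slope[j - 1] > 0 and slope[j] < 0:
            idx.append(int(firsts[j]))
            kind.append(1)
        elif slope[j - 1] < 0 and slope[j] > 0:
            idx.append(int(firsts[j]))
            kind.append(-1)
    return np.array(idx, dtype=int), np.array(kind, dtype=int)


class _Extremum:
    """Node in the doubly linked alternating extrema sequence."""

    __slots__ = ("kind", "first", "last", "value", "prev", "next", "alive")

    def __init__(self, kind: int, first: int, last: int, value: float):
        self.kind = kind      # +1 max, -1 min
        self.first = first    # first index of the value run
        self.last = last      # last index of the value run
        self.value = value
        self.prev: "_Extremum | None" = None
        self.next: "_Extremum | None" = None
        self.alive = True


def _extrema_sequence(values: np.ndarray) -> list[_Extremum]:
    """Alternating min/max sequence including boundary extrema.

    The first and last samples (or their flat runs) are treated as extrema
    of the type implied by the adjacent slope, so that a rise out of a flat
    baseline starts an event and a fall back to baseline ends one.
    """
    firsts, lasts, rv = _value_runs(values)
    m = rv.size
    if m < 2:
        return []
    slope = np.sign(np.diff(rv))
    nodes: list[_Extremum] = []
    nodes.append(_Extremum(-1 if slope[0] > 0 else 1, int(firsts[0]),
                           int(lasts[0]), float(rv[0])))
    for j in range(1, m - 1):
        if slope[j - 1] > 0 and slope[j] < 0:
            nodes.append(_Extremum(1, int(firsts[j]), int(lasts[j]), float(rv[j])))
        elif slope[j - 1] < 0 and slope[j] > 0:
            nodes.append(_Extremum(-1, int(firsts[j]), int(lasts[j]), float(rv[j])))
    nodes.append(_Extremum(-1 if slope[-1] < 0 else 1, int(firsts[-1]),
                           int(lasts[-1]), float(rv[-1])))
    for a, b in zip(nodes, nodes[1:]):
        a.next = b
        b.prev = a
    return nodes


def _pair_fails(a: _Extremum, b: _Extremum, rel: float, abs_: float) -> bool:
    amp = abs(b.value - a.value)
    baseline = min(a.value, b.value)
    return amp < abs_ or amp < rel * baseline


def _prune(head: _Extremum | None, rel: float, abs_: float) -> _Extremum | None:
    """Iteratively remove the smallest-amplitude sub-threshold adjacent pair.

    Removing a pair splices its neighbours together (merging the adjacent
    rises/falls); smallest-first removal makes the result independent of
    scan order.  A lazy heap keyed on (amplitude, position) implements the
    same rule as a full rescan after every removal.
    """
    heap: list[tuple[float, int, int, _Extremum, _Extremum]] = []
    counter = 0
    node = head
    while node is not None and node.next is not None:
        amp = abs(node.next.value - node.value)
        heapq.heappush(heap, (amp, node.first, counter, node, node.next))
        counter += 1
        node = node.next
    while heap:
        amp, _pos, _c, a, b = heapq.heappop(heap)
        if not (a.alive and b.alive and a.next is b):
            continue
        if not _pair_fails(a, b, rel, abs_):
            continue
        left, right = a.prev, b.next
        a.alive = b.alive = False
        if left is not None:
            left.next = right
        if right is not None:
            right.prev = left
        if left is not None and right is not None:
            heapq.heappush(
                heap,
                (abs(right.value - left.value), left.first, counter, left, right),
            )
            counter += 1
        if left is None:
            head = right
    return head


def detect_windflecks(
    series: IrradianceSeries,
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
    abs_threshold: float = DEFAULT_ABS_THRESHOLD,
) -> list[WindfleckEvent]:
    """Detect windflecks by turning-point analysis with dual thresholds.

    Candidate events are (minimum, maximum, next minimum) triples of the
    extrema sequence.  Sub-threshold oscillations — adjacent extremum pairs
    whose amplitude is below ``abs_threshold`` or below ``rel_threshold``
    times the lower of the two values — are pruned smallest-first with
    neighbour merging, so every retained event's intensity passes both
    thresholds.

    Event endpoint conventions on flat stretches: an event starts at the
    last sample of the flat run preceding its rise and ends at the first
    sample of the flat run following its fall, so a triangular pulse on a
    flat baseline has duration exactly equal to its base.
    """
    if rel_threshold < 0 or abs_threshold < 0:
        raise ValueError("thresholds must be non-negative")
    if not check_uniform(series.times, series.rate):
        raise ValueError("series must be uniformly sampled; split it at gaps first")
    v = series.values
    t = series.times
    nodes = _extrema_sequence(v)
    if not nodes:
        return []
    head: _Extremum | None = nodes[0]
    head = _prune(head, rel_threshold, abs_threshold)

    events: list[WindfleckEvent] = []
    node = head
    while node is not None:
        nxt = node.next
        nxt2 = nxt.next if nxt is not None else None
        if (
            node.kind == -1
            and nxt is not None
            and nxt.kind == 1
            and nxt2 is not None
            and nxt2.kind == -1
        ):
            si = node.last       # rise onset
            pi = nxt.first       # peak (first index of a peak plateau)
            ei = nxt2.first      # fall offset
            baseline = v[si]
            intensity = v[pi] - baseline
            ev = WindfleckEvent(
                start_time=float(t[si]),
                peak_time=float(t[pi]),
                end_time=float(t[ei]),
                baseline=float(baseline),
                peak_ppfd=float(v[pi]),
                intensity=float(intensity),
                duration=float(t[ei] - t[si]),
                integrated_increase=_integrated_increase_idx(series, si, ei),
                start_index=si,
                peak_index=pi,
                end_index=ei,
            )
            events.append(ev)
        node = nxt
    return events


def _integrated_increase_idx(series: IrradianceSeries, si: int, ei: int) -> float:
    t = series.times[si: ei + 1]
    v = series.values[si: ei + 1]
    total = np.trapezoid(v, t)
    chord = 0.5 * (v[0] + v[-1]) * (t[-1] - t[0])
    return float(max(0.0, total - chord))


def integrated_increase(event: WindfleckEvent, series: IrradianceSeries) -> float:
    """Area between the PPFD trace and the start–end chord, µmol m⁻², ≥ 0."""
    si, ei = event.start_index, event.end_index
    if si < 0 or ei < 0:
        si = int(np.searchsorted(series.times, event.start_time))
        ei = int(np.searchsorted(series.times, event.end_time))
    if not (0 <= si < ei < len(series)):
        raise ValueError("event indices outside the series")
    return _integrated_increase_idx(series, si, ei)


def summarize_flecks(events: list[WindfleckEvent], total_time: float) -> FleckSummary:
    """Frequency and mean time between flecks for one record."""
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    n = len(events)
    freq = n / total_time
    if n >= 2:
        ev = sorted(events, key=lambda e: e.start_time)
        gaps = [b.start_time - a.end_time for a, b in zip(ev, ev[1:])]
        mtb = float(np.mean(gaps))
    else:
        mtb = float("nan")
    return FleckSummary(
        n_events=n,
        total_time=float(total_time),
        frequency=float(freq),
        frequency_per_100s=float(freq * 100.0),
        mean_time_between=mtb,
    )


def split_segments(
    times: np.ndarray, values: np.ndarray, rate: float, max_gap_intervals: float = 2.0
) -> list[IrradianceSeries]:
    """Split a record at sampling gaps larger than ``max_gap_intervals``/rate."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(times) > max_gap_intervals / rate)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [times.size]))
    return [
        IrradianceSeries(times[s:e], values[s:e], rate=rate)
        for s, e in zip(starts, ends)
        if e - s >= 2
    ]
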