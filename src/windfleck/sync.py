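"""Multi-rate alignment of PPFD, motion and wind records.

The three instruments start by hand and their clocks disagree by up to a
few seconds.  All streams are first brought to the 100 s⁻¹ PPFD clock:
QOM (nominally 30 s⁻¹) by linear interpolation, wind (1 s⁻¹) by step
extension of each value without interpolation.  The analysis zone is the
candidate zone whose QOM has the largest absolute cross-correlation with
PPFD, and the wind-record shift is the lag maximizing the product of the
PPFD–wind and QOM–wind cross-correlations, restricted to lags where the
QOM–wind correlation is positive (more wind producing less motion is
physically implausible and those lags are ignored).

Cross-correlations are Pearson-normalized per lag on the overlapping
window, making the "largest absolute value" criteria scale-free.  Lags are
integer samples at the common rate (0.01 s resolution); positive lag means
the second series is delayed relative to the first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import UniformSeries

__all__ = [
    "CrossCorrelation",
    "NoValidShiftError",
    "resample_linear",
    "resample_step",
    "cross_correlation",
    "select_zone",
    "estimate_wind_shift",
    "ResampledBundle",
    "build_bundle",
]

DEFAULT_MAX_LAG = 500  # samples at 100 s⁻¹, i.e. ±5 s
COMMON_RATE = 100.0


class NoValidShiftError(RuntimeError):
    """No lag with a positive QOM–wind correlation exists."""


@dataclass
class CrossCorrelation:
    """Pearson cross-correlation on a symmetric integer-lag grid.

    ``values[i]`` is the correlation at ``lags[i]``; NaN where the
    overlapping window of either series has zero variance.
    """

    lags: np.ndarray
    values: np.ndarray
    max_lag: int

    def peak_lag(self, absolute: bool = True) -> int:
        """Lag of the (absolute) maximum correlation; NaNs ignored."""
        vals = np.abs(self.values) if absolute else self.values
        if np.all(np.isnan(vals)):
            raise ValueError("all correlations are undefined")
        return int(self.lags[np.nanargmax(vals)])

    def peak_value(self, absolute: bool = True) -> float:
        vals = np.abs(self.values) if absolute else self.values
        if np.all(np.isnan(vals)):
            return float("nan")
        return float(np.nanmax(vals))


def resample_linear(
    series: UniformSeries, to_rate: float = COMMON_RATE
) -> UniformSeries:
    """Resample by linear interpolation onto a ``to_rate`` grid.

    The output grid starts at the first input timestamp and covers the
    input span; end values are held for any edge extrapolation.
    """
    if len(series) < 2:
        raise ValueError("at least 2 samples are required")
    if series.rate > to_rate:
        raise ValueError("resample_linear only upsamples (from_rate ≤ to_rate)")
    t0, t1 = series.times[0], series.times[-1]
    n_out = int(np.floor((t1 - t0) * to_rate)) + 1
    t_out = t0 + np.arange(n_out) / to_rate
    v_out = np.interp(t_out, series.times, series.values)
    return UniformSeries(t_out, v_out, rate=to_rate)


def resample_step(
    series: UniformSeries, to_rate: float = COMMON_RATE
) -> UniformSeries:
    """Extend each sample, without interpolation, to ``to_rate``.

    Each original value is repeated ``to_rate/from_rate`` times and stamped
    from the start of its interval (giving the bar-like shape of a 1 s⁻¹
    wind record displayed at 100 s⁻¹).
    """
    factor_f = to_rate / series.rate
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-9 or factor < 1:
        raise ValueError("from_rate must divide to_rate")
    v_out = np.repeat(series.values, factor)
    t_out = series.times[0] + np.arange(v_out.size) / to_rate
    return UniformSeries(t_out, v_out, rate=to_rate)


def cross_correlation(
    a: np.ndarray, b: np.ndarray, max_lag: int = DEFAULT_MAX_LAG
) -> CrossCorrelation:
    """Pearson correlation of ``a`` and ``b`` at each integer lag.

    At lag k ≥ 0, ``a[:n−k]`` is paired with ``b[k:]``; a positive lag
    therefore means ``b`` is delayed relative to ``a``.  Lags where either
    overlapping segment has zero variance yield NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size != b.size:
        raise ValueError("inputs must be equal-length 1-D arrays")
    n = a.size
    if n < 2 * max_lag + 2:
        raise ValueError("series too short for the requested max_lag")
    lags = np.arange(-max_lag, max_lag + 1)
    vals = np.empty(lags.size)
    for i, k in enumerate(lags):
        if k >= 0:
            x, y = a[: n - k], b[k:]
        else:
            x, y = a[-k:], b[: n + k]
        xs = x.std()
        ys = y.std()
        if xs == 0 or ys == 0:
            vals[i] = np.nan
        else:
            vals[i] = float(np.mean((x - x.mean()) * (y - y.mean())) / (xs * ys))
    return CrossCorrelation(lags=lags, values=vals, max_lag=int(max_lag))


def select_zone(
    ppfd: np.ndarray,
    qom_by_zone: dict,
    candidate_zones: list,
    max_lag: int = DEFAULT_MAX_LAG,
):
    """Pick the candidate zone with the largest absolute PPFD–QOM correlation.

    Geometric proximity to the light diffuser is resolved by the caller,
    who passes only the near-diffuser zones as candidates.  Ties break to
    the lowest zone id.

    Returns ``(zone_id, CrossCorrelation)`` for the winning zone.
    """
    if not candidate_zones:
        raise ValueError("candidate_zones must be non-empty")
    missing = [z for z in candidate_zones if z not in qom_by_zone]
    if missing:
        raise ValueError(f"unknown candidate zones: {missing}")
    best = None
    for zid in sorted(candidate_zones):
        xc = cross_correlation(ppfd, qom_by_zone[zid], max_lag)
        score = xc.peak_value(absolute=True)
        if best is None or score > best[0]:
            best = (score, zid, xc)
    return best[1], best[2]


def estimate_wind_shift(
    xc_ppfd_wind: CrossCorrelation, xc_qom_wind: CrossCorrelation
) -> int:
    """Mean wind-record shift, in samples, from two cross-correlations.

    Over lags where the QOM–wind correlation is positive, return the lag
    maximizing the product of the PPFD–wind and QOM–wind correlations.
    Raises :class:`NoValidShiftError` when no lag qualifies.
    """
    if not np.array_equal(xc_ppfd_wind.lags, xc_qom_wind.lags):
        raise ValueError("cross-correlations must share the same lag grid")
    valid = xc_qom_wind.values > 0
    if not np.any(valid & np.isfinite(xc_ppfd_wind.values)):
        raise NoValidShiftError(
            "no lag with positive QOM–wind correlation and finite PPFD–wind "
            "correlation"
        )
    product = np.where(valid, xc_ppfd_wind.values * xc_qom_wind.values, -np.inf)
    product = np.where(np.isfinite(product), product, -np.inf)
    return int(xc_ppfd_wind.lags[np.argmax(product)])


@dataclass
class ResampledBundle:
    """PPFD, per-zone QOM and wind on a common 100 s⁻¹ clock."""

    times: np.ndarray
    ppfd: np.ndarray
    qom: dict
    wind: np.ndarray
    common_rate: float = COMMON_RATE
    applied_shifts: dict | None = None


def build_bundle(
    ppfd_series: UniformSeries,
    qom_series_by_zone: dict,
    wind_series: UniformSeries,
    common_rate: float = COMMON_RATE,
) -> ResampledBundle:
    """Resample the three streams and trim them to their common length.

    QOM is linearly interpolated, wind step-extended, PPFD taken as-is;
    all arrays start at their own first timestamp (clock offsets are
    estimated afterwards, not assumed away).
    """
    qom_rs = {z: resample_linear(s, common_rate) for z, s in qom_series_by_zone.items()}
    wind_rs = resample_step(wind_series, common_rate)
    n = min(
        len(ppfd_series),
        len(wind_rs),
        *(len(s) for s in qom_rs.values()),
    )
    return ResampledBundle(
        times=np.arange(n) / common_rate,
        ppfd=ppfd_series.values[:n].copy(),
        qom={z: s.values[:n].copy() for z, s in qom_rs.items()},
        wind=wind_rs.values[:n].copy(),
        common_rate=common_rate,
    )
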