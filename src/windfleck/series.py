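"""Time-series containers shared across the pipeline.

Three instrument streams are handled: photosynthetic photon flux density
(PPFD) logged at 100 samples/s, per-zone quantity of motion (QOM) derived
from video at the camera frame rate (nominally 30 frames/s, one sample per
consecutive frame pair), and wind speed logged at 1 sample/s.  Each is a
thin wrapper around a pair of aligned numpy arrays (timestamps in seconds,
values) plus the nominal sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UniformSeries",
    "WindSeries",
    "MotionSeries",
    "IrradianceSeries",
    "check_uniform",
]

#: tolerance on timestamp spacing for a series to count as uniformly sampled
SPACING_TOL = 1e-9


def check_uniform(times: np.ndarray, rate: float, tol: float = 1e-6) -> bool:
    """Return True if ``times`` is uniformly spaced at 1/rate within ``tol`` s."""
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        return True
    dt = np.diff(times)
    return bool(np.all(np.abs(dt - 1.0 / rate) <= tol))


@dataclass
class UniformSeries:
    """A uniformly sampled scalar time series.

    Parameters
    ----------
    times
        Sample timestamps in seconds, strictly increasing.
    values
        Sample values, same length as ``times``.
    rate
        Nominal sampling rate in s⁻¹.
    """

    times: np.ndarray
    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError(
                f"times and values must have equal length, got "
                f"{self.times.shape} vs {self.values.shape}"
            )
        if self.times.ndim != 1:
            raise ValueError("series arrays must be one-dimensional")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        """Record span in seconds (last minus first timestamp)."""
        if len(self) < 2:
            return 0.0
        return float(self.times[-1] - self.times[0])


@dataclass
class WindSeries(UniformSeries):
    """Wind speed in m s⁻¹, nominally 1 sample/s."""

    rate: float = 1.0

    @property
    def speed(self) -> np.ndarray:
        return self.values


@dataclass
class MotionSeries(UniformSeries):
    """Per-zone quantity of motion (QOM), one value per frame pair.

    QOM is unitless; the raw (uncorrected) statistic lies in [0, 3] when
    computed with the mean-square or mean-absolute per-channel aggregation.
    """

    rate: float = 30.0
    zone_id: str = ""
    corrected: bool = False

    @property
    def qom(self) -> np.ndarray:
        return self.values


@dataclass
class IrradianceSeries(UniformSeries):
    """PPFD in µmol m⁻² s⁻¹, nominally 100 samples/s."""

    rate: float = 100.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.values < 0):
            raise ValueError("PPFD values must be non-negative")

    @property
    def ppfd(self) -> np.ndarray:
        return self.values
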