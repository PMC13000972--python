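"""Seeded generators emulating the four field-data streams.

Every downstream stage of the pipeline can be exercised without any
recorded data: the generators produce gusty non-negative wind, canopy
motion responding exponentially to wind with a lag, fleck-bearing PPFD
whose event rate scales with motion, frame sequences whose pixel changes
track a known motion signal, and randomized-block trait tables with known
variance components.  All draws come from an explicit integer seed; there
is no global random state, so identical parameters give bit-identical
output.

What is emulated and what is not: wind is a clipped AR(1) process with
Poisson-arriving exponential gusts — the simplest process that clusters
gusts the way wind eddies cluster windflecks; fleck pulses are symmetric
triangles, which makes duration, intensity and integrated increase
analytically checkable; no spectra, sun angle, penumbra or canopy 3-D
geometry are simulated, and there is no aerodynamic (drag/stiffness)
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .motion import FrameSequence
from .series import IrradianceSeries, MotionSeries, WindSeries

__all__ = [
    "WindModelParams",
    "MotionModelParams",
    "FleckModelParams",
    "TraitSimParams",
    "TrueFleck",
    "gen_wind",
    "gen_motion",
    "gen_ppfd",
    "gen_frames",
    "gen_trait_table",
    "true_heritability",
]


@dataclass(frozen=True)
class WindModelParams:
    """Clipped AR(1) wind with Poisson gusts, 1 sample/s.

    Defaults cover the 0–2.4 m s⁻¹ range seen in gentle field conditions:
    mean 1.2 m s⁻¹, lag-1 autocorrelation 0.7, about one gust every 20 s
    with mean excess 0.8 m s⁻¹.
    """

    mean_speed: float = 1.2        # m s⁻¹, stationary mean including gusts
    ar_coefficient: float = 0.7    # lag-1 autocorrelation, in [0, 1)
    gust_rate: float = 0.05        # gust arrivals s⁻¹
    gust_amplitude: float = 0.8    # mean gust excess, m s⁻¹
    noise_sd: float = 0.25         # AR innovation SD, m s⁻¹
    max_speed: float = 2.4         # m s⁻¹, ceiling of the emulated session
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.ar_coefficient < 1):
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.gust_rate < 0 or self.gust_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("rates, amplitudes and SDs must be non-negative")
        if self.max_speed <= self.mean_speed:
            raise ValueError("max_speed must exceed mean_speed")


@dataclass(frozen=True)
class MotionModelParams:
    """Exponential motion response QOM(t) = a·exp(b·wind(t − lag))·(1+ε)."""

    base_motion: float = 0.002   # a, QOM at zero wind; must be > 0
    wind_gain: float = 1.2       # b, (m s⁻¹)⁻¹
    lag: float = 0.1             # s, delay of the canopy response behind wind
    noise_cv: float = 0.2        # CV of the multiplicative log-normal noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_motion <= 0:
            raise ValueError("base_motion must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


@dataclass(frozen=True)
class FleckModelParams:
    """Fleck-bearing PPFD: baseline plus triangular pulses plus noise.

    The event process is inhomogeneous with instantaneous rate
    rate_gain·QOM(t).  Duration defaults put ~95% of flecks between 0.05
    and 0.44 s; amplitudes are log-normal with median ≈ 40 µmol m⁻² s⁻¹.
    """

    baseline_ppfd: float = 100.0            # µmol m⁻² s⁻¹
    rate_gain: float = 250.0                # flecks s⁻¹ per QOM unit
    amplitude_dist: tuple = (3.7, 0.6)      # (log-mean, log-sd), µmol m⁻² s⁻¹
    duration_dist: tuple = (-1.91, 0.55)    # (log-mean, log-sd), s
    sensor_noise_sd: float = 0.5            # µmol m⁻² s⁻¹
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_ppfd <= 0:
            raise ValueError("baseline_ppfd must be positive")
        if self.rate_gain < 0 or self.sensor_noise_sd < 0:
            raise ValueError("rate_gain and sensor_noise_sd must be non-negative")


@dataclass(frozen=True)
class TraitSimParams:
    """Randomized-block trait panel with known variance components."""

    n_varieties: int = 10
    n_blocks: int = 3
    grand_mean: float = 80.0
    var_variety: float = 4.0   # σ²_V
    var_block: float = 0.0
    var_residual: float = 1.0  # σ²_r
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_varieties < 2 or self.n_blocks < 2:
            raise ValueError("need at least 2 varieties and 2 blocks")
        if min(self.var_variety, self.var_block, self.var_residual) < 0:
            raise ValueError("variances must be non-negative")


@dataclass(frozen=True)
class TrueFleck:
    """Ground-truth event injected by :func:`gen_ppfd`."""

    start_time: float
    peak_time: float
    end_time: float
    amplitude: float
    duration: float


def gen_wind(params: WindModelParams, duration: float) -> WindSeries:
    """Simulate wind speed at 1 sample/s for ``duration`` seconds.

    The AR(1) base level is offset so that the stationary mean including
    the gust contribution equals ``mean_speed``; speeds are clipped to
    [0, max_speed] — the generator emulates a gentle-condition session
    whose documented coverage is 0–2.4 m s⁻¹, and an unbounded gust tail
    would drive the exponential motion response far outside the range the
    downstream QOM binning is built for.
    """
    if duration < 1:
        raise ValueError("duration must be at least 1 s")
    n = int(np.floor(duration))
    rng = np.random.default_rng(params.seed)
    phi = params.ar_coefficient
    mu = params.mean_speed - params.gust_rate * params.gust_amplitude / (1 - phi)
    x = np.empty(n)
    innov = rng.normal(0.0, params.noise_sd, n)
    counts = rng.poisson(params.gust_rate, n)
    gusts = np.array(
        [rng.exponential(params.gust_amplitude, c).sum() if c else 0.0 for c in counts]
    )
    prev = params.gust_rate * params.gust_amplitude / (1 - phi)  # stationary mean of x
    for t in range(n):
        prev = phi * prev + innov[t] + gusts[t]
        x[t] = prev
    speeds = np.clip(mu + x, 0.0, params.max_speed)
    return WindSeries(np.arange(n, dtype=float), speeds, rate=1.0)


def _wind_at(wind: WindSeries, t: np.ndarray) -> np.ndarray:
    """Step (sample-and-hold) lookup of the 1 s⁻¹ wind at arbitrary times."""
    idx = np.floor(t - wind.times[0]).astype(int)
    idx = np.clip(idx, 0, len(wind) - 1)
    return wind.values[idx]


def gen_motion(
    wind: WindSeries,
    params: MotionModelParams,
    rate: float = 30.0,
) -> tuple[MotionSeries, float]:
    """Canopy QOM responding exponentially to wind with a fixed lag.

    QOM(t) = a·exp(b·wind(t − lag))·m(t) with m a unit-mean log-normal
    multiplier of CV ≈ noise_cv, so the series is strictly positive.
    Returns the series and the true lag in seconds.
    """
    if len(wind) == 0:
        raise ValueError("wind series is empty")
    span = len(wind) / wind.rate
    if abs(params.lag) >= span:
        raise ValueError("lag exceeds the wind record length")
    n = int(round(span * rate))
    t = wind.times[0] + np.arange(n) / rate
    w = _wind_at(wind, t - params.lag)
    clean = params.base_motion * np.exp(params.wind_gain * w)
    if params.noise_cv > 0:
        rng = np.random.default_rng(params.seed)
        sigma = np.sqrt(np.log1p(params.noise_cv**2))
        mult = rng.lognormal(-0.5 * sigma**2, sigma, n)
    else:
        mult = 1.0
    return (
        MotionSeries(t, clean * mult, rate=rate, zone_id="synthetic"),
        params.lag,
    )


def gen_ppfd(
    motion: MotionSeries,
    params: FleckModelParams,
    rate: float = 100.0,
    extra_events: list | None = None,
) -> tuple[IrradianceSeries, list[TrueFleck]]:
    """PPFD with windfleck pulses whose rate follows the motion signal.

    Event starts arrive as an inhomogeneous binomial thinning with
    per-sample probability rate_gain·QOM(t)/rate.  Each event adds a
    symmetric triangular pulse whose peak is snapped to the sample grid.
    ``extra_events`` is an optional list of (start_time, amplitude,
    duration_s) tuples injected deterministically.

    Returns the series and the ground-truth event list sorted by start.
    """
    if len(motion) == 0:
        raise ValueError("motion series is empty")
    span = len(motion) / motion.rate
    n = int(round(span * rate))
    t0 = motion.times[0]
    t = t0 + np.arange(n) / rate
    qom_at = np.interp(t, motion.times, motion.values)
    rng = np.random.default_rng(params.seed)

    events: list[tuple[float, float, float]] = []
    if params.rate_gain > 0:
        p = np.clip(params.rate_gain * qom_at / rate, 0.0, 1.0)
        starts = np.flatnonzero(rng.random(n) < p)
        amps = rng.lognormal(*params.amplitude_dist, starts.size)
        durs = rng.lognormal(*params.duration_dist, starts.size)
        events.extend(zip(t[starts], amps, durs))
    if extra_events:
        events.extend((float(s), float(a), float(d)) for s, a, d in extra_events)

    ppfd = np.full(n, params.baseline_ppfd)
    truth: list[TrueFleck] = []
    for start, amp, dur in events:
        si = int(round((start - t0) * rate))
        half = max(1, int(round(dur * rate / 2)))
        pi, ei = si + half, si + 2 * half
        if si < 0 or ei >= n:
            continue
        ramp = np.concatenate(
            (np.linspace(0, 1, half + 1), np.linspace(1, 0, half + 1)[1:])
        )
        ppfd[si: ei + 1] += amp * ramp
        truth.append(
            TrueFleck(
                start_time=float(t[si]),
                peak_time=float(t[pi]),
                end_time=float(t[ei]),
                amplitude=float(amp),
                duration=float(2 * half / rate),
            )
        )
    if params.sensor_noise_sd > 0:
        ppfd = ppfd + rng.normal(0.0, params.sensor_noise_sd, n)
    ppfd = np.clip(ppfd, 0.0, None)
    truth.sort(key=lambda ev: ev.start_time)
    return IrradianceSeries(t, ppfd, rate=rate), truth


def gen_frames(
    motion: MotionSeries,
    image_size: tuple[int, int] = (64, 64),
    texture_scale: float = 8.0,
    seed: int = 0,
    displacement_gain: float = 1.0,
    border: int = 8,
) -> FrameSequence:
    """Textured frames whose foreground shifts with a known motion signal.

    Each frame pair's horizontal displacement is ``displacement_gain``
    times the corresponding motion value (sub-pixel shifts rendered by
    linear interpolation); a static band of ``border`` pixels around the
    frame is left unmoved, suitable as reference zones.  A motion series of
    length L yields L+1 frames.
    """
    h, w = image_size
    if h < 32 or w < 32:
        raise ValueError("image_size must be at least 32×32")
    if texture_scale >= min(h, w):
        raise ValueError("texture_scale must be smaller than the image dimensions")
    if border * 2 >= min(h, w):
        raise ValueError("border too wide for the image")

    disp = displacement_gain * motion.values
    pos = np.concatenate(([0.0], np.cumsum(disp)))  # position per frame
    pad = int(np.ceil(np.abs(pos).max())) + 2
    rng = np.random.default_rng(seed)
    tex = np.empty((h, w + 2 * pad, 3))
    for ch in range(3):
        noise = rng.standard_normal((h, w + 2 * pad))
        sm = ndimage.gaussian_filter(noise, sigma=texture_scale / 3.0)
        lo, hi_ = sm.min(), sm.max()
        tex[..., ch] = 0.05 + 0.9 * (sm - lo) / (hi_ - lo if hi_ > lo else 1.0)

    cols = np.arange(w)
    static = tex[:, pad: pad + w, :]
    inner = np.zeros((h, w), dtype=bool)
    inner[border: h - border, border: w - border] = True

    frames = np.empty((pos.size, h, w, 3))
    for k, p in enumerate(pos):
        src = cols + pad + p
        f = np.floor(src).astype(int)
        frac = src - f
        shifted = tex[:, f, :] * (1 - frac)[None, :, None] + tex[:, f + 1, :] * frac[None, :, None]
        frame = static.copy()
        frame[inner] = shifted[inner]
        frames[k] = frame
    frames = np.clip(frames, 0.0, 1.0)
    timestamps = np.arange(pos.size) / motion.rate
    return FrameSequence(frames, timestamps, nominal_rate=motion.rate)


def true_heritability(params: TraitSimParams) -> float:
    """Broad-sense heritability implied by the simulation parameters."""
    denom = params.var_variety + params.var_residual / params.n_blocks
    return params.var_variety / denom if denom > 0 else 0.0


def gen_trait_table(params: TraitSimParams) -> pd.DataFrame:
    """One trait value per variety × block: mean + variety + block + residual."""
    rng = np.random.default_rng(params.seed)
    nv, nb = params.n_varieties, params.n_blocks
    v_eff = rng.normal(0.0, np.sqrt(params.var_variety), nv)
    b_eff = rng.normal(0.0, np.sqrt(params.var_block), nb)
    resid = rng.normal(0.0, np.sqrt(params.var_residual), (nv, nb))
    rows = []
    for i in range(nv):
        for j in range(nb):
            rows.append(
                {
                    "cultivar": f"V{i + 1:02d}",
                    "block": f"B{j + 1}",
                    "value": params.grand_mean + v_eff[i] + b_eff[j] + resid[i, j],
                }
            )
    return pd.DataFrame(rows)
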