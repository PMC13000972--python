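"""Trait formulas, binning schemes, cultivar indices and heritability.

Biomechanical traits: natural frequency N = 3/T from the time T for three
oscillations of a displaced tiller; leaf mass per area LMA = LM/LA;
height-to-mass ratio HM = H/TM; leaf-to-stem mass ratio LTM = LM/(TM−LM).

Series are grouped into wind-speed classes of 0.3 m s⁻¹ and QOM into 15
exponentially growing classes with edges exp(linspace(−11, −2, 16)), which
equilibrates observation counts on the log scale; windfleck frequency per
class is the event count over the time spent in the class, with classes
holding one or fewer events reported as missing.

Cultivar-level indices: motion sensitivity (mean QOM / mean wind) and
light modulation efficiency (fleck frequency / mean QOM), each centred and
scaled across the cultivar panel.

Broad-sense heritability over variety means with n biological replicates
(blocks):  H² = σ²_V / (σ²_V + σ²_r / n).  The variance components are
estimated by the ANOVA method of moments on the variety × block means;
repeatability is the proportion of total variance explained by blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Allometry",
    "VarianceDecomposition",
    "natural_frequency",
    "allometry",
    "wind_class_edges",
    "qom_class_edges",
    "bin_series",
    "time_in_class",
    "frequency_by_class",
    "event_mean_value",
    "cultivar_indices",
    "variance_decomposition",
]

WIND_CLASS_WIDTH = 0.3  # m s⁻¹
QOM_LOG_LO, QOM_LOG_HI, QOM_N_EDGES = -11.0, -2.0, 16


def natural_frequency(t_three_oscillations: float) -> float:
    """Natural frequency N = 3/T, s⁻¹, from the time for three oscillations."""
    if t_three_oscillations <= 0:
        raise ValueError("oscillation time must be positive")
    return 3.0 / t_three_oscillations


@dataclass(frozen=True)
class Allometry:
    """Leaf mass per area (g cm⁻²), height-to-mass (cm g⁻¹), leaf-to-stem
    mass ratio (g g⁻¹; NaN when total mass does not exceed leaf mass)."""

    lma: float
    hm: float
    ltm: float


def allometry(
    height_cm: float, total_mass_g: float, leaf_mass_g: float, leaf_area_cm2: float
) -> Allometry:
    """LMA = LM/LA, HM = H/TM, LTM = LM/(TM − LM).

    LTM requires TM > LM (a tiller with no stem mass has no defined ratio)
    and is returned as NaN otherwise; LMA and HM are still computed.
    """
    if leaf_area_cm2 <= 0 or total_mass_g <= 0:
        raise ValueError("leaf area and total mass must be positive")
    lma = leaf_mass_g / leaf_area_cm2
    hm = height_cm / total_mass_g
    ltm = (
        leaf_mass_g / (total_mass_g - leaf_mass_g)
        if total_mass_g > leaf_mass_g
        else float("nan")
    )
    return Allometry(lma=lma, hm=hm, ltm=ltm)


def wind_class_edges(max_speed: float, width: float = WIND_CLASS_WIDTH) -> np.ndarray:
    """Wind-speed class edges 0, width, 2·width, … covering ``max_speed``."""
    if width <= 0:
        raise ValueError("class width must be positive")
    n = int(np.ceil(max_speed / width)) + 1
    return np.arange(n + 1) * width


def qom_class_edges() -> np.ndarray:
    """The 16 exponential QOM class edges e⁻¹¹ … e⁻² (15 classes)."""
    return np.exp(np.linspace(QOM_LOG_LO, QOM_LOG_HI, QOM_N_EDGES))


def bin_series(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open class labels per sample: k where edges[k] ≤ v < edges[k+1].

    Samples outside [edges[0], edges[-1]) — including QOM values of exactly
    0, which fall below the lowest exponential edge — get label −1.
    """
    values = np.asarray(values, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing with ≥ 2 entries")
    labels = np.digitize(values, edges, right=False) - 1
    labels[(values < edges[0]) | (values >= edges[-1])] = -1
    return labels


def time_in_class(labels: np.ndarray, rate: float, n_classes: int) -> np.ndarray:
    """Seconds spent in each class: sample count × sampling interval."""
    counts = np.bincount(labels[labels >= 0], minlength=n_classes)
    return counts / rate


def frequency_by_class(
    event_labels: np.ndarray,
    time_per_class: np.ndarray,
    min_events: int = 2,
    on_zero_time: str = "error",
) -> tuple[np.ndarray, np.ndarray]:
    """Windfleck frequency (s⁻¹) per class.

    Classes with fewer than ``min_events`` events are reported as NaN (the
    convention of not showing classes with one or fewer flecks).  An event
    assigned to a class in which the series spent no time is an
    inconsistency and raises by default; because events are labelled by
    their MEAN series value over the event window, the mean can fall in a
    class no single sample occupies, so ``on_zero_time="missing"`` reports
    such classes as NaN instead.  Returns ``(frequency, counts)`` arrays of
    length ``len(time_per_class)``.
    """
    event_labels = np.asarray(event_labels, dtype=int)
    n_classes = len(time_per_class)
    counts = np.bincount(
        event_labels[event_labels >= 0], minlength=n_classes
    )[:n_classes]
    bad = (counts > 0) & (np.asarray(time_per_class) <= 0)
    if np.any(bad):
        if on_zero_time == "error":
            raise ValueError("events assigned to a class with zero time in class")
        counts = np.where(bad, 0, counts)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(time_per_class > 0, counts / time_per_class, 0.0)
    freq = np.where(counts < min_events, np.nan, freq)
    return freq, counts


def event_mean_value(
    events, times: np.ndarray, values: np.ndarray
) -> np.ndarray:
    """Mean of a synchronized series over each event's [start, end] window.

    Used to assign each windfleck a single QOM / wind value for class
    binning; the mean over the event is robust to 0.01 s timing jitter.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    out = np.empty(len(events))
    for i, ev in enumerate(events):
        si = int(np.searchsorted(times, ev.start_time - 1e-12))
        ei = int(np.searchsorted(times, ev.end_time + 1e-12))
        ei = max(ei, si + 1)
        out[i] = values[si:ei].mean()
    return out


def cultivar_indices(table: pd.DataFrame) -> pd.DataFrame:
    """Motion sensitivity and light modulation efficiency per cultivar.

    ``table`` needs columns ``cultivar``, ``mean_qom``, ``mean_wind`` and
    ``fleck_frequency``.  Raw ratios are mean QOM / mean wind and fleck
    frequency / mean QOM; the ``*_z`` columns are centred and scaled
    (sample SD) across the cultivar panel so 0 is the panel average.  A
    degenerate axis (zero spread) reports 0 for every cultivar.
    """
    required = {"cultivar", "mean_qom", "mean_wind", "fleck_frequency"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if len(table) < 2:
        raise ValueError("at least 2 cultivars are required")
    if (table["mean_wind"] <= 0).any() or (table["mean_qom"] <= 0).any():
        raise ValueError("mean wind and mean QOM must be positive")
    out = table[["cultivar"]].copy()
    out["motion_sensitivity"] = table["mean_qom"] / table["mean_wind"]
    out["light_modulation_efficiency"] = (
        table["fleck_frequency"] / table["mean_qom"]
    )
    for col in ("motion_sensitivity", "light_modulation_efficiency"):
        sd = out[col].std(ddof=1)
        out[col + "_z"] = 0.0 if sd == 0 else (out[col] - out[col].mean()) / sd
    return out


@dataclass(frozen=True)
class VarianceDecomposition:
    """Variance components and derived ratios for one trait.

    ``sigma2_V`` is the variance among variety means (method-of-moments
    corrected unless requested otherwise), ``sigma2_r`` the residual
    variance of variety × block means about their variety mean,
    ``sigma2_block`` the block variance component.  ``h2`` is broad-sense
    heritability σ²_V/(σ²_V + σ²_r/n_blocks), clipped to [0, 1];
    ``repeatability`` is σ²_block over the total.
    """

    sigma2_V: float
    sigma2_r: float
    sigma2_block: float
    n_varieties: int
    n_blocks: int
    repeatability: float
    h2: float


def variance_decomposition(
    table: pd.DataFrame,
    value_col: str = "value",
    correct_bias: bool = True,
    floor_components: bool = True,
) -> VarianceDecomposition:
    """Method-of-moments variance decomposition of a variety × block table.

    Technical replicates (multiple rows per cultivar × block) are averaged
    first.  σ̂²_r is the pooled sample variance of the variety × block
    means about their variety mean.  With ``correct_bias`` (default) the
    among-variety-means variance is corrected by σ̂²_r/n_blocks — the
    ANOVA estimator of σ²_V; without it the raw variance of variety means
    is used (the literal plug of the heritability formula, upward-biased
    at small panel sizes).  ``floor_components=False`` leaves σ̂²_V and
    σ̂²_block possibly negative, which is what unbiased averaging across
    replicate panels requires.
    """
    for col in ("cultivar", "block", value_col):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    cell = (
        table.groupby(["cultivar", "block"], sort=True)[value_col]
        .mean()
        .unstack("block")
    )
    if cell.isna().any().any():
        raise ValueError("every cultivar × block cell needs at least one value")
    y = cell.to_numpy(dtype=float)
    nv, nb = y.shape
    if nv < 2 or nb < 2:
        raise ValueError("need at least 2 varieties and 2 blocks")

    variety_means = y.mean(axis=1)
    block_means = y.mean(axis=0)
    sigma2_r = float(y.var(axis=1, ddof=1).mean())
    sigma2_v = float(np.var(variety_means, ddof=1))
    if correct_bias:
        sigma2_v -= sigma2_r / nb
    sigma2_block = float(np.var(block_means, ddof=1)) - sigma2_r / nv
    if floor_components:
        sigma2_v = max(0.0, sigma2_v)
        sigma2_block = max(0.0, sigma2_block)

    denom = sigma2_v + sigma2_r / nb
    h2 = sigma2_v / denom if denom > 0 else 0.0
    h2 = float(np.clip(h2, 0.0, 1.0))
    total = sigma2_block + sigma2_v + sigma2_r
    rep = sigma2_block / total if total > 0 else 0.0
    rep = float(np.clip(rep, 0.0, 1.0))
    return VarianceDecomposition(
        sigma2_V=sigma2_v,
        sigma2_r=sigma2_r,
        sigma2_block=sigma2_block,
        n_varieties=nv,
        n_blocks=nb,
        repeatability=rep,
        h2=h2,
    )
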