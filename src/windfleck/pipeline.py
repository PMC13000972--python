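"""End-to-end orchestration: generate/load → QOM → sync → detect → bin → summarize.

The pipeline runs one or more recordings (one per cultivar) through the
full chain and writes every intermediate table as CSV, so individual
stages can be re-run against external data.  A run-report (plain-text
key=value) records the seed, a hash of the configuration, the chosen
analysis zone and the estimated inter-stream shifts, making every output
traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .flecks import detect_windflecks, summarize_flecks
from .io import events_to_frame, summary_to_frame, write_series_csv
from .motion import ZoneGrid, qom_series, subtract_reference
from .series import IrradianceSeries, MotionSeries, WindSeries
from .stats import (
    bin_series,
    cultivar_indices,
    event_mean_value,
    frequency_by_class,
    qom_class_edges,
    time_in_class,
    variance_decomposition,
    wind_class_edges,
)
from .sync import (
    NoValidShiftError,
    build_bundle,
    cross_correlation,
    estimate_wind_shift,
    select_zone,
)
from .synthetic import (
    FleckModelParams,
    MotionModelParams,
    TraitSimParams,
    WindModelParams,
    gen_frames,
    gen_motion,
    gen_ppfd,
    gen_trait_table,
    gen_wind,
)

logger = logging.getLogger("windfleck")

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

EXPECTED_RATES = {"ppfd_rate": 100.0, "qom_rate": 30.0, "wind_rate": 1.0}


@dataclass
class RunConfig:
    """Validated run configuration (see ``validate_config``)."""

    seed: int = 0
    out_dir: str = "windfleck_out"
    rel_threshold: float = 0.05
    abs_threshold: float = 5.0
    max_lag: int = 500
    ppfd_rate: float = 100.0
    qom_rate: float = 30.0
    wind_rate: float = 1.0
    wind_class_width: float = 0.3
    candidate_zones: list | None = None
    zone_map: list | None = None
    plot_polygon: list | None = None
    reference_zones: list | None = None
    inputs: dict = field(default_factory=dict)
    synthetic: dict | None = None
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def digest(self) -> str:
        # hash only the parameters that affect results (not output paths or
        # logging), so identical analyses are recognizably identical
        payload = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("out_dir", "log_level")
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Return the list of named violations (empty when the config is valid)."""
    v: list[str] = []
    for name, expected in EXPECTED_RATES.items():
        if getattr(config, name) != expected:
            v.append(f"{name}: expected {expected} s^-1, got {getattr(config, name)}")
    if config.rel_threshold < 0:
        v.append(f"rel_threshold: must be non-negative, got {config.rel_threshold}")
    if config.abs_threshold < 0:
        v.append(f"abs_threshold: must be non-negative, got {config.abs_threshold}")
    if config.max_lag <= 0:
        v.append(f"max_lag: must be positive, got {config.max_lag}")
    if config.wind_class_width <= 0:
        v.append(f"wind_class_width: must be positive, got {config.wind_class_width}")
    if config.zone_map is not None:
        zm = np.asarray(config.zone_map)
        if zm.shape != (9, 16):
            v.append(f"zone_map: must be 9×16 cells, got shape {zm.shape}")
    if config.synthetic is None:
        for key in ("ppfd", "wind"):
            if key not in config.inputs:
                v.append(f"inputs.{key}: required when no synthetic block is present")
            elif not Path(config.inputs[key]).exists():
                v.append(f"inputs.{key}: path {config.inputs[key]} does not exist")
        if "qom" not in config.inputs and "frames_dir" not in config.inputs:
            v.append("inputs: either qom or frames_dir is required")
    edges = qom_class_edges()
    if np.any(np.diff(edges) <= 0):  # defensive; fixed scheme
        v.append("qom class edges are not strictly increasing")
    return v


def _shift_array(a: np.ndarray, lag: int) -> np.ndarray:
    """Advance ``a`` by ``lag`` samples (positive lag = series was delayed),
    holding edge values so the length is preserved."""
    if lag == 0:
        return a.copy()
    out = np.empty_like(a)
    if lag > 0:
        out[:-lag] = a[lag:]
        out[-lag:] = a[-1]
    else:
        out[-lag:] = a[:lag]
        out[:-lag] = a[0]
    return out


def _default_zone_map() -> np.ndarray:
    # simple 8-zone default: pairs of grid columns; real zone layouts are a
    # required user input
    zm = np.zeros((9, 16), dtype=int)
    for c in range(16):
        zm[:, c] = c // 2
    return zm


def _derive_seed(base: int, *offsets: int) -> int:
    h = hashlib.sha256(("/".join(map(str, (base,) + offsets))).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _synthetic_recording(config: RunConfig, name: str, index: int, overrides: dict):
    """Generate one cultivar's wind/motion/ppfd (and optional frames→QOM)."""
    syn = config.synthetic
    duration = float(syn.get("duration_s", 120.0))
    # by default every cultivar of a panel experiences the same wind session,
    # so cultivar indices compare motion responses at equal wind
    wind_index = 0 if syn.get("shared_wind", True) else index
    wind_p = WindModelParams(
        **{**syn.get("wind", {}), "seed": _derive_seed(config.seed, wind_index, 0)}
    )
    motion_kwargs = {**syn.get("motion", {}), **overrides}
    motion_p = MotionModelParams(
        **{**motion_kwargs, "seed": _derive_seed(config.seed, index, 1)}
    )
    fleck_p = FleckModelParams(
        **{**syn.get("fleck", {}), "seed": _derive_seed(config.seed, index, 2)}
    )
    wind = gen_wind(wind_p, duration)
    motion, _lag = gen_motion(wind, motion_p, rate=config.qom_rate)
    ppfd, truth = gen_ppfd(motion, fleck_p, rate=config.ppfd_rate)

    frames_cfg = syn.get("frames")
    if frames_cfg:
        frames = gen_frames(
            motion,
            image_size=tuple(frames_cfg.get("image_size", (64, 64))),
            texture_scale=float(frames_cfg.get("texture_scale", 8.0)),
            seed=_derive_seed(config.seed, index, 3),
            displacement_gain=float(frames_cfg.get("displacement_gain", 1.0)),
        )
        grid = _grid_from_config(config, frames.frame_shape)
        zones, ref = qom_series(frames, grid)
        qom_by_zone = {
            z: subtract_reference(s, ref) for z, s in zones.items()
        }
    else:
        qom_by_zone = {0: motion}
    return wind, qom_by_zone, ppfd, truth


def _grid_from_config(config: RunConfig, frame_shape) -> ZoneGrid:
    h, w = frame_shape
    if config.plot_polygon is not None:
        poly = config.plot_polygon
    else:
        b = 8
        poly = [(b, b), (w - b - 1, b), (w - b - 1, h - b - 1), (b, h - b - 1)]
    zm = (
        np.asarray(config.zone_map)
        if config.zone_map is not None
        else _default_zone_map()
    )
    if config.reference_zones is not None:
        refs = config.reference_zones
    else:
        refs = [[(0, 0), (w - 1, 0), (w - 1, 3), (0, 3)]]
    return ZoneGrid(plot_polygon=poly, zone_map=zm, reference_zones=refs)


def _load_recording(config: RunConfig):
    from .io import read_frames_png, read_series_csv

    ppfd = read_series_csv(config.inputs["ppfd"], "ppfd", rate=config.ppfd_rate)
    wind = read_series_csv(config.inputs["wind"], "wind", rate=config.wind_rate)
    if "frames_dir" in config.inputs:
        frames = read_frames_png(config.inputs["frames_dir"], config.qom_rate)
        grid = _grid_from_config(config, frames.frame_shape)
        zones, ref = qom_series(frames, grid)
        qom_by_zone = {z: subtract_reference(s, ref) for z, s in zones.items()}
    else:
        qom = read_series_csv(config.inputs["qom"], "motion", rate=config.qom_rate)
        qom_by_zone = {0: qom}
    return wind, qom_by_zone, ppfd, None


def _process_recording(config: RunConfig, name: str, wind, qom_by_zone, ppfd, out: Path):
    """QOM → sync → detect → bin for one recording; returns summary rows."""
    report: dict = {}
    bundle = build_bundle(ppfd, qom_by_zone, wind, common_rate=config.ppfd_rate)
    candidates = (
        config.candidate_zones
        if config.candidate_zones is not None
        else sorted(bundle.qom)
    )
    # short records cannot support the full lag window
    max_lag = min(config.max_lag, (len(bundle.times) - 2) // 2)
    zone, xc_pq = select_zone(bundle.ppfd, bundle.qom, candidates, max_lag)
    try:
        qom_shift = xc_pq.peak_lag(absolute=True)
    except ValueError:  # degenerate (constant) stream: no defined correlation
        qom_shift = 0
    xc_pw = cross_correlation(bundle.ppfd, bundle.wind, max_lag)
    xc_qw = cross_correlation(bundle.qom[zone], bundle.wind, max_lag)
    try:
        wind_shift = estimate_wind_shift(xc_pw, xc_qw)
        shift_ok = True
    except NoValidShiftError:
        wind_shift, shift_ok = 0, False
    logger.info(
        "[sync:%s] zone=%s qom_shift=%d wind_shift=%d (valid=%s)",
        name, zone, qom_shift, wind_shift, shift_ok,
    )
    qom_aligned = _shift_array(bundle.qom[zone], qom_shift)
    wind_aligned = _shift_array(bundle.wind, wind_shift)

    ppfd_series = IrradianceSeries(bundle.times, bundle.ppfd, rate=config.ppfd_rate)
    events = detect_windflecks(
        ppfd_series, config.rel_threshold, config.abs_threshold
    )
    total_time = len(bundle.times) / config.ppfd_rate
    summary = summarize_flecks(events, total_time)
    logger.info("[flecks:%s] %d events, %.3f s^-1", name, summary.n_events,
                summary.frequency)

    # class binning on the synchronized streams
    qedges = qom_class_edges()
    wedges = wind_class_edges(max(wind_aligned.max(), 0.3), config.wind_class_width)
    qlab = bin_series(qom_aligned, qedges)
    wlab = bin_series(wind_aligned, wedges)
    qtime = time_in_class(qlab, config.ppfd_rate, len(qedges) - 1)
    wtime = time_in_class(wlab, config.ppfd_rate, len(wedges) - 1)
    if events:
        ev_q = event_mean_value(events, bundle.times, qom_aligned)
        ev_w = event_mean_value(events, bundle.times, wind_aligned)
        qfreq, qcount = frequency_by_class(
            bin_series(ev_q, qedges), qtime, on_zero_time="missing"
        )
        wfreq, wcount = frequency_by_class(
            bin_series(ev_w, wedges), wtime, on_zero_time="missing"
        )
    else:
        qfreq = np.full(len(qedges) - 1, np.nan)
        wfreq = np.full(len(wedges) - 1, np.nan)
        qcount = np.zeros(len(qedges) - 1, dtype=int)
        wcount = np.zeros(len(wedges) - 1, dtype=int)

    # outputs
    qom_df = pd.DataFrame(
        {
            "time_s": bundle.times,
            "zone_id": zone,
            "qom_synchronized": qom_aligned,
        }
    )
    qom_df.to_csv(out / f"{name}_qom.csv", index=False)
    events_to_frame(events).to_csv(out / f"{name}_events.csv", index=False)
    summary_to_frame(summary).to_csv(out / f"{name}_fleck_summary.csv", index=False)
    pd.DataFrame(
        {
            "scheme": "qom_exponential",
            "class_lo": qedges[:-1],
            "class_hi": qedges[1:],
            "time_in_class_s": qtime,
            "n_events": qcount,
            "frequency_per_s": qfreq,
        }
    ).to_csv(out / f"{name}_freq_by_qom_class.csv", index=False)
    pd.DataFrame(
        {
            "scheme": "wind_linear",
            "class_lo": wedges[:-1],
            "class_hi": wedges[1:],
            "time_in_class_s": wtime,
            "n_events": wcount,
            "frequency_per_s": wfreq,
        }
    ).to_csv(out / f"{name}_freq_by_wind_class.csv", index=False)

    report.update(
        {
            f"{name}.zone": zone,
            f"{name}.qom_shift_samples": qom_shift,
            f"{name}.wind_shift_samples": wind_shift,
            f"{name}.wind_shift_valid": shift_ok,
            f"{name}.peak_ppfd_qom_corr": round(xc_pq.peak_value(), 6),
            f"{name}.n_events": summary.n_events,
        }
    )
    row = {
        "cultivar": name,
        "mean_qom": float(np.mean(qom_aligned)),
        "mean_wind": float(np.mean(wind_aligned)),
        "fleck_frequency": summary.frequency,
    }
    return report, row


def run_pipeline(config: RunConfig) -> dict:
    """Run the full chain; returns the run-report dict (also written to disk)."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    report: dict = {
        "pipeline_version": __version__,
        "seed": config.seed,
        "config_sha256": config.digest(),
    }
    rows = []
    if config.synthetic is not None:
        cultivars = config.synthetic.get("cultivars") or [{"name": "synthetic"}]
        for i, cdef in enumerate(cultivars):
            cdef = dict(cdef)
            name = cdef.pop("name", f"cultivar{i + 1}")
            wind, qom_by_zone, ppfd, _truth = _synthetic_recording(
                config, name, i, cdef
            )
            rep, row = _process_recording(config, name, wind, qom_by_zone, ppfd, out)
            report.update(rep)
            rows.append(row)
        traits_cfg = config.synthetic.get("traits")
        if traits_cfg is not None:
            tp = TraitSimParams(
                **{**traits_cfg, "seed": _derive_seed(config.seed, 9999)}
            )
            table = gen_trait_table(tp)
            table.to_csv(out / "trait_table.csv", index=False)
            vd = variance_decomposition(table)
            pd.DataFrame(
                [
                    {
                        "trait": "simulated",
                        "sigma2_V": vd.sigma2_V,
                        "sigma2_r": vd.sigma2_r,
                        "sigma2_block": vd.sigma2_block,
                        "repeatability": vd.repeatability,
                        "H2": vd.h2,
                    }
                ]
            ).to_csv(out / "variance_decomposition.csv", index=False)
            report["traits.H2"] = round(vd.h2, 6)
    else:
        wind, qom_by_zone, ppfd, _ = _load_recording(config)
        rep, row = _process_recording(
            config, "recording", wind, qom_by_zone, ppfd, out
        )
        report.update(rep)
        rows.append(row)

    if len(rows) >= 2:
        cultivar_indices(pd.DataFrame(rows)).to_csv(
            out / "cultivar_indices.csv", index=False
        )

    with open(out / "run_report.txt", "w") as fh:
        for k, v in report.items():
            fh.write(f"{k}={v}\n")
    return report
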