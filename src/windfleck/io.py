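"""CSV and PNG-stack input/output for the pipeline's tables and frames."""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .flecks import FleckSummary, WindfleckEvent
from .motion import FrameSequence
from .series import IrradianceSeries, MotionSeries, UniformSeries, WindSeries

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "events_to_frame",
    "write_events_csv",
    "read_events_csv",
    "summary_to_frame",
    "read_frames_png",
    "write_frames_png",
]


def write_series_csv(series: UniformSeries, path, value_col: str = "value") -> None:
    pd.DataFrame({"time_s": series.times, value_col: series.values}).to_csv(
        path, index=False
    )


def read_series_csv(path, kind: str = "generic", rate: float | None = None):
    """Read a (time_s, value) CSV as the requested series type.

    ``kind`` is one of generic/wind/motion/ppfd; the sampling rate is
    inferred from the median spacing when not given.
    """
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c != "time_s"]
    if "time_s" not in df.columns or not cols:
        raise ValueError(f"{path}: expected columns time_s and a value column")
    t = df["time_s"].to_numpy(float)
    v = df[cols[0]].to_numpy(float)
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 1.0
    cls = {
        "generic": UniformSeries,
        "wind": WindSeries,
        "motion": MotionSeries,
        "ppfd": IrradianceSeries,
    }[kind]
    return cls(t, v, rate=rate)


def events_to_frame(events: list[WindfleckEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start_s": e.start_time,
                "peak_s": e.peak_time,
                "end_s": e.end_time,
                "baseline": e.baseline,
                "intensity": e.intensity,
                "duration_s": e.duration,
                "integrated_increase": e.integrated_increase,
            }
            for e in events
        ],
        columns=[
            "start_s",
            "peak_s",
            "end_s",
            "baseline",
            "intensity",
            "duration_s",
            "integrated_increase",
        ],
    )


def write_events_csv(events: list[WindfleckEvent], path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def summary_to_frame(summary: FleckSummary) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "n_events": summary.n_events,
                "total_time_s": summary.total_time,
                "frequency_per_s": summary.frequency,
                "frequency_per_100s": summary.frequency_per_100s,
                "mean_time_between_s": summary.mean_time_between,
            }
        ]
    )


def write_frames_png(frames: FrameSequence, directory) -> list[str]:
    """Write frames as zero-padded, lexicographically ordered PNG files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(len(frames)):
        p = directory / f"frame_{i:06d}.png"
        iio.imwrite(p, (frames.frames[i] * 255).round().astype(np.uint8))
        paths.append(str(p))
    return paths


def read_frames_png(directory, nominal_rate: float = 30.0) -> FrameSequence:
    """Read a directory of PNGs (lexicographic order) as a frame sequence."""
    directory = Path(directory)
    files = sorted(
        f for f in os.listdir(directory) if f.lower().endswith(".png")
    )
    if not files:
        raise ValueError(f"no PNG files in {directory}")
    stack = np.stack([iio.imread(directory / f) for f in files]).astype(float) / 255.0
    if stack.ndim == 3:  # grayscale → replicate channels
        stack = np.repeat(stack[..., None], 3, axis=-1)
    stack = stack[..., :3]
    times = np.arange(stack.shape[0]) / nominal_rate
    return FrameSequence(stack, times, nominal_rate=nominal_rate)
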