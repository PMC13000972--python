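"""Quantity-of-motion (QOM) computation by frame differencing.

Wind-induced canopy movement shows up as frame-to-frame changes in pixel
values.  For each pair of consecutive RGB frames and each analysis zone,
the per-pixel absolute channel differences are aggregated within the zone
and summed over the red, green and blue channels, giving one scalar per
frame pair — the quantity of motion.  With the default aggregation (mean of
squared absolute differences) QOM is 0 when nothing changes and 3 when the
whole zone flips between pure white and pure black.

Camera/sensor noise also produces pixel differences, so one or more static
reference zones (bare soil outside the plot) are tracked alongside the
canopy zones; their mean QOM is subtracted from every canopy zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely import contains_xy
from shapely.geometry import Polygon

from .series import MotionSeries

__all__ = [
    "FrameSequence",
    "ZoneGrid",
    "frame_qom",
    "qom_series",
    "subtract_reference",
    "QOM_STATISTICS",
]

QOM_STATISTICS = ("mean_square", "mean_abs", "centered_variance")


@dataclass
class FrameSequence:
    """An ordered stack of RGB frames with timestamps.

    ``frames`` has shape (n_frames, height, width, 3) with channel values in
    [0, 1]; ``timestamps`` are seconds, strictly increasing.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    nominal_rate: float = 30.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (n, H, W, 3)")
        if self.frames.shape[0] != self.timestamps.size:
            raise ValueError("one timestamp per frame required")
        if self.timestamps.size >= 2 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.frames.size and (self.frames.min() < 0 or self.frames.max() > 1):
            raise ValueError("channel values must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


def _polygon_mask(vertices, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside a polygon.

    Vertices are (col, row) pixel coordinates, 0-based, origin top-left.
    """
    poly = Polygon(vertices)
    h, w = shape
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    return contains_xy(poly, cols.ravel(), rows.ravel()).reshape(h, w)


@dataclass
class ZoneGrid:
    """Partition of a plot polygon into a 16×9 cell grid grouped into zones.

    Parameters
    ----------
    plot_polygon
        Vertices of the plot outline as (col, row) pixel coordinates.
    zone_map
        Integer array of shape (n_rows, n_cols); entry (r, c) is the zone id
        of grid cell (r, c), or -1 for cells excluded from analysis.
    reference_zones
        Polygons (vertex lists) of static regions outside the plot used for
        noise correction.
    """

    plot_polygon: list
    zone_map: np.ndarray
    reference_zones: list = field(default_factory=list)
    n_cols: int = 16
    n_rows: int = 9

    def __post_init__(self) -> None:
        self.zone_map = np.asarray(self.zone_map, dtype=int)
        if self.zone_map.shape != (self.n_rows, self.n_cols):
            raise ValueError(
                f"zone_map must have shape ({self.n_rows}, {self.n_cols})"
            )

    def zone_ids(self) -> list[int]:
        ids = np.unique(self.zone_map)
        return [int(z) for z in ids if z >= 0]

    def zone_masks(self, frame_shape: tuple[int, int]) -> dict[int, np.ndarray]:
        """Boolean pixel masks per zone id for frames of ``frame_shape``."""
        inside = _polygon_mask(self.plot_polygon, frame_shape)
        cols = np.array([c for c, r in self.plot_polygon])
        rows = np.array([r for c, r in self.plot_polygon])
        c0, c1 = cols.min(), cols.max()
        r0, r1 = rows.min(), rows.max()
        h, w = frame_shape
        cgrid, rgrid = np.meshgrid(np.arange(w), np.arange(h))
        # cell index of each pixel over the polygon bounding box
        ci = np.floor((cgrid - c0) / (c1 - c0) * self.n_cols).astype(int)
        ri = np.floor((rgrid - r0) / (r1 - r0) * self.n_rows).astype(int)
        ci = np.clip(ci, 0, self.n_cols - 1)
        ri = np.clip(ri, 0, self.n_rows - 1)
        masks: dict[int, np.ndarray] = {}
        for zid in self.zone_ids():
            cell_sel = self.zone_map[ri, ci] == zid
            mask = inside & cell_sel
            if not mask.any():
                raise ValueError(f"zone {zid} has no pixels in a {frame_shape} frame")
            masks[zid] = mask
        return masks

    def reference_masks(self, frame_shape: tuple[int, int]) -> list[np.ndarray]:
        masks = []
        for verts in self.reference_zones:
            m = _polygon_mask(verts, frame_shape)
            if not m.any():
                raise ValueError("a reference zone has no pixels")
            masks.append(m)
        return masks


def frame_qom(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    zone: np.ndarray,
    statistic: str = "mean_square",
) -> float:
    """Quantity of motion between two frames over one zone.

    Per channel, the per-pixel absolute difference |Δ| is aggregated within
    the zone by ``statistic`` and the three channel values are summed:

    - ``mean_square``   mean of |Δ|² (default; 0 for identical frames, 3 for
      a uniform white↔black flip)
    - ``mean_abs``      mean of |Δ|
    - ``centered_variance``  population variance of |Δ| within the zone

    Parameters
    ----------
    frame_a, frame_b
        RGB arrays of identical shape (H, W, 3), channel values in [0, 1].
    zone
        Boolean mask of shape (H, W) selecting the zone's pixels.
    """
    frame_a = np.asarray(frame_a, dtype=float)
    frame_b = np.asarray(frame_b, dtype=float)
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must have identical shape")
    zone = np.asarray(zone, dtype=bool)
    if zone.shape != frame_a.shape[:2]:
        raise ValueError("zone mask must match frame height and width")
    if not zone.any():
        raise ValueError("zone is empty")
    if statistic not in QOM_STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {QOM_STATISTICS}")

    diff = np.abs(frame_a[zone] - frame_b[zone])  # (n_pixels, 3)
    if statistic == "mean_square":
        per_channel = np.mean(diff**2, axis=0)
    elif statistic == "mean_abs":
        per_channel = np.mean(diff, axis=0)
    else:  # centered_variance
        per_channel = np.var(diff, axis=0)
    return float(per_channel.sum())


def qom_series(
    frames: FrameSequence,
    grid: ZoneGrid,
    statistic: str = "mean_square",
) -> tuple[dict[int, MotionSeries], MotionSeries]:
    """Per-zone QOM series plus the mean reference-zone series.

    Each consecutive frame pair yields one sample, timestamped at the pair
    midpoint.  The reference series is the mean over all reference zones
    (empty reference list → all-zero reference series).
    """
    if len(frames) < 2:
        raise ValueError("at least two frames are required")
    shape = frames.frame_shape
    zmasks = grid.zone_masks(shape)
    rmasks = grid.reference_masks(shape)
    n_pairs = len(frames) - 1
    mid_times = 0.5 * (frames.timestamps[:-1] + frames.timestamps[1:])

    zone_vals = {zid: np.empty(n_pairs) for zid in zmasks}
    ref_vals = np.zeros(n_pairs)
    for i in range(n_pairs):
        a, b = frames.frames[i], frames.frames[i + 1]
        for zid, m in zmasks.items():
            zone_vals[zid][i] = frame_qom(a, b, m, statistic)
        if rmasks:
            ref_vals[i] = np.mean([frame_qom(a, b, m, statistic) for m in rmasks])

    out = {
        zid: MotionSeries(mid_times.copy(), v, rate=frames.nominal_rate,
                          zone_id=str(zid))
        for zid, v in zone_vals.items()
    }
    ref = MotionSeries(mid_times.copy(), ref_vals, rate=frames.nominal_rate,
                       zone_id="reference")
    return out, ref


def subtract_reference(
    zone_series: MotionSeries,
    reference_series: MotionSeries,
    floor_at_zero: bool = True,
) -> MotionSeries:
    """Subtract the mean reference-zone QOM from a canopy-zone QOM series.

    Negative results are floored at 0 by default: downstream analyses
    log-transform QOM, and non-positive values are excluded from the
    exponential class binning anyway.
    """
    if len(zone_series) != len(reference_series):
        raise ValueError("zone and reference series must have equal length")
    if not np.allclose(zone_series.times, reference_series.times, atol=1e-9):
        raise ValueError("zone and reference series must share timestamps")
    corrected = zone_series.qom - reference_series.qom
    if floor_at_zero:
        corrected = np.maximum(corrected, 0.0)
    return MotionSeries(
        zone_series.times.copy(),
        corrected,
        rate=zone_series.rate,
        zone_id=zone_series.zone_id,
        corrected=True,
    )
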