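"""Occupancy, spike-count, and firing-rate maps on the fixed arena grid.

The arena is tiled by square pixels (20 x 20 bins of 2 cm by default) with
the SW corner at the origin.  Binning is half-open — a point on an interior
bin edge belongs to the higher bin — with the last bin closed so the far
walls are included.  Pixels visited for less than ``min_occupancy`` seconds
(0.1 s by default) are excluded from every rate computation, and smoothing
is a mask-aware Gaussian: kernel weights are renormalised over the valid
support so excluded pixels neither contribute to nor receive values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic_data import ArenaSpec, Trajectory, nearest_frame_index

DEFAULT_MIN_OCCUPANCY_S = 0.1


@dataclass(frozen=True)
class GridSpec:
    """Square binning grid derived from the arena geometry."""

    side_length: float = 40.0
    bin_size: float = 2.0

    def __post_init__(self) -> None:
        n = self.side_length / self.bin_size
        if self.bin_size <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError("side_length must be a positive multiple of bin_size")

    @classmethod
    def from_arena(cls, arena: ArenaSpec) -> "GridSpec":
        return cls(side_length=arena.side_length, bin_size=arena.bin_size)

    @property
    def n_bins(self) -> int:
        return int(round(self.side_length / self.bin_size))

    def bin_index(self, coord) -> np.ndarray:
        """Map coordinates to bin indices (half-open bins; last bin closed)."""
        c = np.asarray(coord, dtype=float)
        idx = np.floor(c / self.bin_size).astype(int)
        return np.clip(idx, 0, self.n_bins - 1)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate arrays of shape (n_bins, n_bins).

        Array axis 0 indexes y (rows, increasing North), axis 1 indexes x.
        """
        c = (np.arange(self.n_bins) + 0.5) * self.bin_size
        return np.meshgrid(c, c)[0], np.meshgrid(c, c)[1]


@dataclass(frozen=True)
class OccupancyMap:
    """Per-pixel dwell time in seconds; shape (n_bins, n_bins), [y, x]."""

    dwell: np.ndarray
    grid: GridSpec
    total_duration: float

    def probabilities(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Occupancy probabilities p(x_i), normalised over `mask` (or all pixels)."""
        m = np.ones_like(self.dwell, dtype=bool) if mask is None else mask
        total = self.dwell[m].sum()
        if total <= 0:
            raise ValueError("no dwell time on the requested pixels")
        p = np.zeros_like(self.dwell)
        p[m] = self.dwell[m] / total
        return p


@dataclass(frozen=True)
class SpikeCountMap:
    counts: np.ndarray
    grid: GridSpec


@dataclass(frozen=True)
class RateMap:
    """Firing-rate map with a validity mask.

    ``rate`` holds Hz on valid pixels and NaN elsewhere.  ``overall_rate``
    is F = sum_i p_i f_i over the valid support (equivalently total spikes
    over total dwell on valid pixels).  ``dwell`` is carried along so the
    occupancy weighting survives smoothing.
    """

    rate: np.ndarray
    valid: np.ndarray
    grid: GridSpec
    dwell: np.ndarray
    smoothed: bool = False

    @property
    def overall_rate(self) -> float:
        d = self.dwell[self.valid].sum()
        if d <= 0:
            return 0.0
        return float(np.nansum(self.rate[self.valid] * self.dwell[self.valid]) / d)

    def masked(self, mask: np.ndarray) -> "RateMap":
        """Restrict validity to ``mask`` (used for between-trial comparisons)."""
        new_valid = self.valid & mask
        rate = np.where(new_valid, self.rate, np.nan)
        return replace(self, rate=rate, valid=new_valid)


def bin_occupancy(trajectory: Trajectory, grid: GridSpec) -> OccupancyMap:
    """Accumulate one frame period of dwell per position sample."""
    inside = (
        (trajectory.x >= 0)
        & (trajectory.x <= grid.side_length)
        & (trajectory.y >= 0)
        & (trajectory.y <= grid.side_length)
    )
    if not inside.all():
        bad = int(np.flatnonzero(~inside)[0])
        raise ValueError(f"trajectory sample {bad} lies outside the arena")
    ix = grid.bin_index(trajectory.x)
    iy = grid.bin_index(trajectory.y)
    dt = 1.0 / trajectory.frame_rate
    dwell = np.zeros((grid.n_bins, grid.n_bins))
    np.add.at(dwell, (iy, ix), dt)
    return OccupancyMap(dwell=dwell, grid=grid, total_duration=trajectory.duration)


def bin_spikes(spikes: np.ndarray, trajectory: Trajectory, grid: GridSpec) -> SpikeCountMap:
    """Assign each spike to the pixel of the temporally nearest frame."""
    spikes = np.asarray(spikes, dtype=float)
    counts = np.zeros((grid.n_bins, grid.n_bins))
    if spikes.size:
        t0, t1 = trajectory.t[0], trajectory.t[0] + trajectory.duration
        out = (spikes < t0) | (spikes > t1)
        if out.any():
            raise ValueError(
                f"spike at t={spikes[out][0]:.6f}s outside the trajectory span "
                f"[{t0:.6f}, {t1:.6f}]"
            )
        idx = nearest_frame_index(spikes, trajectory.t)
        ix = grid.bin_index(trajectory.x[idx])
        iy = grid.bin_index(trajectory.y[idx])
        np.add.at(counts, (iy, ix), 1.0)
    return SpikeCountMap(counts=counts, grid=grid)


def compute_rate_map(
    occ: OccupancyMap,
    counts: SpikeCountMap,
    min_occupancy: float = DEFAULT_MIN_OCCUPANCY_S,
) -> RateMap:
    """Rate = spikes / dwell on pixels meeting the occupancy criterion."""
    if occ.grid != counts.grid:
        raise ValueError("occupancy and spike-count maps use different grids")
    valid = occ.dwell >= min_occupancy
    if not valid.any():
        raise ValueError("no valid pixels: every pixel fails the occupancy criterion")
    rate = np.full_like(occ.dwell, np.nan)
    rate[valid] = counts.counts[valid] / occ.dwell[valid]
    return RateMap(rate=rate, valid=valid, grid=occ.grid, dwell=occ.dwell, smoothed=False)


def gaussian_kernel(radius_bins: int = 2, sigma_bins: float = 1.0) -> np.ndarray:
    """Truncated, normalised 2-D Gaussian kernel on a (2r+1)^2 support."""
    if radius_bins < 0:
        raise ValueError("kernel radius must be nonnegative")
    ax = np.arange(-radius_bins, radius_bins + 1, dtype=float)
    gx, gy = np.meshgrid(ax, ax)
    k = np.exp(-(gx**2 + gy**2) / (2.0 * sigma_bins**2)) if radius_bins else np.ones((1, 1))
    return k / k.sum()


def smooth_rate_map(
    rmap: RateMap, radius_bins: int = 2, sigma_bins: float = 1.0
) -> RateMap:
    """Mask-renormalised Gaussian smoothing of the rate map.

    Each valid pixel becomes the kernel-weighted mean of the valid pixels in
    its neighbourhood, with weights renormalised over the valid support.
    Invalid pixels stay NaN and do not leak into their neighbours.
    """
    if not rmap.valid.any():
        raise ValueError("rate map has no valid pixels")
    kernel = gaussian_kernel(radius_bins, sigma_bins)
    filled = np.where(rmap.valid, rmap.rate, 0.0)
    num = ndimage.convolve(filled, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(rmap.valid.astype(float), kernel, mode="constant", cval=0.0)
    sm = np.full_like(rmap.rate, np.nan)
    sm[rmap.valid] = num[rmap.valid] / den[rmap.valid]
    return replace(rmap, rate=sm, smoothed=True)


def common_valid_mask(map_a: RateMap, map_b: RateMap) -> np.ndarray:
    """Pixels meeting the occupancy criterion in both sessions."""
    if map_a.grid != map_b.grid:
        raise ValueError("rate maps use different grids")
    mask = map_a.valid & map_b.valid
    if not mask.any():
        raise ValueError("no common valid pixels between the two maps")
    return mask


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------


def read_tracking_csv(path: str | Path, frame_rate: float | None = None) -> Trajectory:
    """Read a `time_s,x_cm,y_cm` tracking export."""
    df = pd.read_csv(path)
    required = {"time_s", "x_cm", "y_cm"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: tracking CSV must have columns {sorted(required)}")
    t = df["time_s"].to_numpy(dtype=float)
    if frame_rate is None:
        if len(t) < 2:
            raise ValueError(f"{path}: cannot infer frame rate from a single frame")
        frame_rate = float(round(1.0 / float(np.median(np.diff(t)))))
    return Trajectory(
        t=t, x=df["x_cm"].to_numpy(dtype=float), y=df["y_cm"].to_numpy(dtype=float),
        frame_rate=frame_rate,
    )


def read_spikes_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: spike CSV must have a time_s column")
    return np.sort(df["time_s"].to_numpy(dtype=float))


def write_rate_map(rmap: RateMap, path: str | Path, min_occupancy: float | None = None) -> None:
    """Write a rate map as a commented-header text grid plus its mask."""
    path = Path(path)
    header = (
        f"# rate map ({'smoothed' if rmap.smoothed else 'raw'}); Hz; NaN = excluded pixel\n"
        f"# grid: {rmap.grid.n_bins} x {rmap.grid.n_bins} bins of {rmap.grid.bin_size} cm; "
        f"row 0 = South, col 0 = West\n"
        + (f"# min_occupancy_s: {min_occupancy}\n" if min_occupancy is not None else "")
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, rmap.rate, fmt="%.6f")
        fh.write("# validity mask (1 = valid)\n")
        np.savetxt(fh, rmap.valid.astype(int), fmt="%d")


def read_rate_map(path: str | Path, grid: GridSpec | None = None) -> RateMap:
    grid = grid or GridSpec()
    n = grid.n_bins
    rows = [
        line.split()
        for line in Path(path).read_text().splitlines()
        if line and not line.startswith("#")
    ]
    data = np.array([[float(v) for v in row] for row in rows])
    if data.shape != (2 * n, n):
        raise ValueError(f"{path}: expected {2 * n} x {n} numeric rows, got {data.shape}")
    rate, mask = data[:n], data[n:].astype(bool)
    dwell = mask.astype(float)  # occupancy is not stored; equal weights on valid pixels
    return RateMap(rate=np.where(mask, rate, np.nan), valid=mask, grid=grid, dwell=dwell,
                   smoothed="smoothed" in Path(path).read_text().splitlines()[0])
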