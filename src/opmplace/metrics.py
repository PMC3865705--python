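"""Per-unit spatial-coding metrics.

Implements the standard place-cell measures on masked rate maps: peak and
occupancy-weighted mean rate, Skaggs spatial information (bits/s and the
headline bits/spike), place-field detection by edge-contiguity at 10% of
the peak, rate-weighted center of mass (COM), between-trial COM shift and
Pearson map similarity, COM-to-object proximity, and the waveform-based
unit screen (>= 250 us peak-to-trough width for putative pyramidal cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, stats

from .ratemap import OccupancyMap, RateMap, common_valid_mask
from .synthetic_data import ObjectLayout, ObjectSpec

FIELD_THRESHOLD_FRACTION = 0.1  # of peak rate
FIELD_MIN_PIXELS = 8
PYRAMIDAL_MIN_SPIKE_WIDTH_US = 250.0

ComScope = Literal["full-map", "field-restricted"]


@dataclass(frozen=True)
class RateSummary:
    peak_rate: float
    mean_rate: float


@dataclass(frozen=True)
class SIResult:
    bits_per_second: float
    bits_per_spike: float


@dataclass(frozen=True)
class PlaceField:
    """Edge-connected suprathreshold pixel region containing the peak."""

    pixels: frozenset[tuple[int, int]]  # (row, col) = (y, x) indices
    size_cm2: float
    peak_pixel: tuple[int, int]
    peak_rate: float

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)


@dataclass(frozen=True)
class ComPoint:
    x: float
    y: float
    scope: ComScope

    def distance_to(self, other: "ComPoint") -> float:
        return math.hypot(other.x - self.x, other.y - self.y)


@dataclass(frozen=True)
class SimilarityResult:
    r: float  # NaN when not computable
    n_pixels: int
    reason: str | None = None


def summarize_rates(rmap: RateMap, occ: OccupancyMap) -> RateSummary:
    """Peak (max over valid pixels) and occupancy-weighted mean rate."""
    if not rmap.valid.any():
        raise ValueError("rate map has no valid pixels")
    rates = rmap.rate[rmap.valid]
    p = occ.probabilities(rmap.valid)[rmap.valid]
    return RateSummary(peak_rate=float(rates.max()), mean_rate=float((p * rates).sum()))


def spatial_information(rmap: RateMap, occ: OccupancyMap) -> SIResult:
    """Skaggs information  I = sum_i p_i f_i log2(f_i / F).

    p_i is the occupancy probability, f_i the pixel rate, F the overall
    rate; the sum runs over valid pixels with the 0*log0 := 0 convention.
    The summation form is an information *rate* (bits/s); dividing by F
    gives the conventionally reported bits per spike.
    """
    if not rmap.valid.any():
        raise ValueError("rate map has no valid pixels")
    f = rmap.rate[rmap.valid]
    p = occ.probabilities(rmap.valid)[rmap.valid]
    overall = float((p * f).sum())
    if overall <= 0:
        raise ValueError("silent unit: overall rate is zero, SI undefined")
    pos = f > 0
    bits_per_second = float(np.sum(p[pos] * f[pos] * np.log2(f[pos] / overall)))
    return SIResult(bits_per_second=bits_per_second, bits_per_spike=bits_per_second / overall)


def detect_place_field(
    rmap: RateMap,
    threshold_fraction: float = FIELD_THRESHOLD_FRACTION,
    min_pixels: int = FIELD_MIN_PIXELS,
) -> PlaceField | None:
    """Find the place field, if any.

    The field is the 4-connected component of valid pixels with rate at or
    above ``threshold_fraction`` of the unit's peak that contains the peak
    pixel itself; it must span at least ``min_pixels`` pixels.  Other
    suprathreshold components are discarded.  Returns None (not an error)
    when the map is silent or the peak component is too small.
    """
    if not rmap.valid.any():
        raise ValueError("rate map has no valid pixels")
    rates = np.where(rmap.valid, rmap.rate, -np.inf)
    peak = rates.max()
    if peak <= 0:
        return None
    supra = rmap.valid & (rmap.rate >= threshold_fraction * peak)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # edge connectivity
    labels, _ = ndimage.label(supra, structure=structure)
    peak_pixel = np.unravel_index(int(np.argmax(rates)), rates.shape)
    lab = labels[peak_pixel]
    component = np.argwhere(labels == lab)
    if len(component) < min_pixels:
        return None
    return PlaceField(
        pixels=frozenset((int(r), int(c)) for r, c in component),
        size_cm2=len(component) * rmap.grid.bin_size**2,
        peak_pixel=(int(peak_pixel[0]), int(peak_pixel[1])),
        peak_rate=float(peak),
    )


def center_of_mass(
    rmap: RateMap,
    scope: ComScope = "full-map",
    fieldref: PlaceField | None = None,
) -> ComPoint:
    """Rate-weighted centroid of pixel centers, in cm.

    ``scope='field-restricted'`` limits the weighting to the pixels of
    ``fieldref`` (detected on the same map when not given).
    """
    mask = rmap.valid.copy()
    if scope == "field-restricted":
        if fieldref is None:
            fieldref = detect_place_field(rmap)
        if fieldref is None:
            raise ValueError("no place field to restrict the COM to")
        fm = np.zeros_like(mask)
        rows, cols = zip(*fieldref.pixels)
        fm[list(rows), list(cols)] = True
        mask &= fm
    elif scope != "full-map":
        raise ValueError(f"unknown COM scope {scope!r}")
    w = np.where(mask, np.nan_to_num(rmap.rate, nan=0.0), 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total rate in the requested scope")
    ny, nx = w.shape
    xs = (np.arange(nx) + 0.5) * rmap.grid.bin_size
    ys = (np.arange(ny) + 0.5) * rmap.grid.bin_size
    x = float((w.sum(axis=0) * xs).sum() / total)
    y = float((w.sum(axis=1) * ys).sum() / total)
    return ComPoint(x=x, y=y, scope=scope)


def com_shift(
    map_a: RateMap,
    map_b: RateMap,
    scope: ComScope = "field-restricted",
) -> dict:
    """COM displacement between two trials, on the common valid mask.

    Falls back to full-map COM for a map without a detectable field, so the
    shift is always defined for units firing in both trials; the scopes
    actually used are reported.
    """
    mask = common_valid_mask(map_a, map_b)
    coms = []
    scopes = []
    for m in (map_a, map_b):
        restricted = m.masked(mask)
        use_scope = scope
        if scope == "field-restricted" and detect_place_field(restricted) is None:
            use_scope = "full-map"
        coms.append(center_of_mass(restricted, scope=use_scope))
        scopes.append(use_scope)
    vector = (coms[1].x - coms[0].x, coms[1].y - coms[0].y)
    return {
        "distance": math.hypot(*vector),
        "vector": vector,
        "com_a": coms[0],
        "com_b": coms[1],
        "scopes": tuple(scopes),
    }


def similarity_score(map_a: RateMap, map_b: RateMap) -> SimilarityResult:
    """Pearson correlation of the two maps over their common valid pixels."""
    mask = common_valid_mask(map_a, map_b)
    a = map_a.rate[mask]
    b = map_b.rate[mask]
    n = int(mask.sum())
    if n < 3:
        return SimilarityResult(r=float("nan"), n_pixels=n, reason="fewer than 3 common pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return SimilarityResult(r=float("nan"), n_pixels=n, reason="constant map on common mask")
    r = float(stats.pearsonr(a, b).statistic)
    return SimilarityResult(r=r, n_pixels=n, reason=None)


def object_proximity(com: ComPoint, objects: ObjectLayout | Sequence[ObjectSpec], trial: str = "T2") -> dict:
    """Distance from a COM to the nearest object center (ties report both)."""
    if isinstance(objects, ObjectLayout):
        objs = objects.objects(trial)
    else:
        objs = tuple(objects)
    if not objs:
        raise ValueError("object layout is empty")
    dists = np.array([math.hypot(com.x - o.center[0], com.y - o.center[1]) for o in objs])
    dmin = float(dists.min())
    labels = [o.label for o, d in zip(objs, dists) if math.isclose(d, dmin, abs_tol=1e-9)]
    return {"labels": labels, "label": labels[0], "distance": dmin}


def screen_unit(spike_width_us: float | None, has_refractory_gap: bool) -> str:
    """Waveform screen: 'putative_pyramidal', 'putative_interneuron', 'rejected'.

    Pyramidal cells need a peak-to-trough width of at least 250 us and a
    clear refractory gap in the autocorrelogram; narrow-spiking units with
    a gap are putative interneurons; anything else is rejected.
    """
    if spike_width_us is None:
        return "rejected"  # no waveform metadata
    if spike_width_us <= 0:
        raise ValueError("spike width must be positive")
    if not has_refractory_gap:
        return "rejected"
    if spike_width_us >= PYRAMIDAL_MIN_SPIKE_WIDTH_US:
        return "putative_pyramidal"
    return "putative_interneuron"
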