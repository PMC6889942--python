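"""Redox-ratio metrics: pixel/voxel maps, surface RR, wound area, volumetric RR.

Surface RR is the arithmetic mean of the pixel-wise NADH/FAD ratio over
wound pixels; volumetric RR the same over wound voxels; normalized wound
area is the wound pixel count at day t divided by the day-0 count (the
pixel size is constant, so it cancels).

Ratios are undefined where the calibrated FAD signal falls below a small
floor (default 1% of the masked median FAD) — an undefined ratio cannot
contribute zero without biasing the mean downward, so the mean divides by
the number of *valid* pixels and both counts are reported.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .errors import ContractError, MetricError
from .frames import (ChannelFrame, Histogram, RedoxMap, SurfaceMetrics,
                     VolumetricMetrics, WoundMask)

DEFAULT_FAD_FLOOR_FRACTION = 0.01
DEFAULT_HIST_BINS = 100
DEFAULT_HIST_RANGE = (0.0, 4.0)


def _as_array(frame, *, require_calibrated: bool) -> np.ndarray:
    if isinstance(frame, ChannelFrame):
        if require_calibrated and not frame.calibrated:
            raise ContractError(
                f"{frame.channel} frame must be calibrated before ratioing")
        return frame.pixels
    return np.asarray(frame, dtype=np.float64)


def redox_map(nadh, fad, mask: WoundMask,
              fad_floor: Optional[float] = None) -> RedoxMap:
    """Pixel/voxel-wise NADH/FAD over the wound mask.

    ``nadh``/``fad`` are calibrated :class:`ChannelFrame` objects (2D) or
    plain arrays (e.g. flat-field-corrected cryo volumes).  The ratio is
    defined where the mask is true and FAD >= ``fad_floor``.
    """
    n = _as_array(nadh, require_calibrated=True)
    f = _as_array(fad, require_calibrated=True)
    if n.shape != f.shape:
        raise MetricError(f"channel shapes differ: {n.shape} vs {f.shape}")
    mask.check_shape(n.shape)
    m = mask.mask
    if not m.any():
        raise MetricError("empty wound mask")
    if fad_floor is None:
        med = float(np.median(f[m]))
        if med <= 0:
            raise MetricError("masked FAD median is zero; supply fad_floor")
        fad_floor = DEFAULT_FAD_FLOOR_FRACTION * med
    if not fad_floor > 0:
        raise MetricError("fad_floor must be positive")
    valid = m & (f >= fad_floor)
    if not valid.any():
        raise MetricError("no valid pixels: FAD below floor everywhere in mask")
    values = np.full(n.shape, np.nan)
    values[valid] = n[valid] / f[valid]
    excluded = 1.0 - valid.sum() / m.sum()
    return RedoxMap(values, valid, n_mask=int(m.sum()), excluded_fraction=float(excluded))


def surface_rr(rmap: RedoxMap, subject=None, group=None, day=None) -> SurfaceMetrics:
    """Mean redox ratio over valid wound pixels (the histogram mean)."""
    if rmap.n_valid == 0:
        raise MetricError("redox map has no valid pixels")
    vals = rmap.defined_values
    return SurfaceMetrics(
        surface_rr=float(vals.mean()), n_pixels=rmap.n_mask, n_valid=rmap.n_valid,
        subject=subject, group=group, day=day)


def normalized_area(n_t: int, n_0: int) -> float:
    """Wound pixel count at day t over the day-0 count; 1 at wounding."""
    if n_0 <= 0:
        raise MetricError("day-0 wound pixel count must be positive")
    if n_t < 0:
        raise MetricError("pixel counts cannot be negative")
    return n_t / n_0


def volumetric_rr(rmap3d: RedoxMap, subject=None, group=None, day=None) -> VolumetricMetrics:
    """Mean redox ratio over valid wound voxels of a 3D map."""
    if rmap3d.n_valid == 0:
        raise MetricError("3D redox map has no valid voxels")
    vals = rmap3d.defined_values
    return VolumetricMetrics(
        volumetric_rr=float(vals.mean()), n_voxels=rmap3d.n_valid,
        subject=subject, group=group, day=day)


def rr_histogram(rmap: RedoxMap, n_bins: int = DEFAULT_HIST_BINS,
                 value_range: Tuple[float, float] = DEFAULT_HIST_RANGE) -> Histogram:
    """Ratio histogram with explicit under/overflow bins; fractions sum to 1."""
    if rmap.n_valid == 0:
        raise MetricError("cannot histogram an empty redox map")
    if n_bins < 1:
        raise MetricError("n_bins must be >= 1")
    lo, hi = value_range
    if not lo < hi:
        raise MetricError("histogram range must satisfy lo < hi")
    vals = rmap.defined_values
    edges = np.linspace(lo, hi, n_bins + 1)
    inner, _ = np.histogram(vals[(vals >= lo) & (vals < hi)], bins=edges)
    under = int((vals < lo).sum())
    over = int((vals >= hi).sum())
    counts = np.concatenate([[under], inner, [over]])
    return Histogram(edges=edges, counts=counts)


def histogram_mean(hist: Histogram) -> float:
    """Mean ratio estimated from in-range bin centres (under/overflow excluded)."""
    inner = hist.counts[1:-1]
    total = inner.sum()
    if total == 0:
        raise MetricError("histogram has no in-range counts")
    return float((hist.centers * inner).sum() / total)
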