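"""Wound segmentation from white-light frames.

The experimental workflow delineates the wound bed visually; this module
standardizes that step as Otsu thresholding of a median-smoothed white-light
image (the open wound is darker than the surrounding shaved skin), followed
by largest-connected-component selection, hole filling and one binary
opening.  Manual masks remain first-class for real data.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology

from .errors import MaskError, SegmentationError
from .frames import ChannelFrame, WoundMask


def segment_wound(white: ChannelFrame, wound_is_dark: bool = True) -> WoundMask:
    """Threshold the white-light frame and post-process into a wound mask."""
    if white.channel != "WHITE":
        raise SegmentationError("segmentation uses the white-light channel")
    smoothed = ndi.median_filter(white.pixels, size=3)
    lo, hi = smoothed.min(), smoothed.max()
    if lo == hi:
        raise SegmentationError(
            "white-light frame has no contrast; supply a manual mask")
    thresh = filters.threshold_otsu(smoothed)
    raw = smoothed < thresh if wound_is_dark else smoothed > thresh
    if not raw.any():
        raise SegmentationError(
            "no pixels on the wound side of the threshold; supply a manual mask")

    labels = measure.label(raw, connectivity=2)  # 8-connectivity
    props = measure.regionprops(labels)
    sizes = np.array([p.area for p in props])
    best = sizes.max()
    candidates = [p for p in props if p.area == best]
    if len(candidates) > 1:
        # wounds are centred by protocol: tie-break on centroid distance
        center = np.array(raw.shape) / 2.0
        candidates.sort(key=lambda p: float(np.sum((np.array(p.centroid) - center) ** 2)))
    mask = labels == candidates[0].label
    mask = ndi.binary_fill_holes(mask)
    mask = morphology.opening(mask, morphology.disk(1))
    if not mask.any():
        raise SegmentationError(
            "mask empty after post-processing; supply a manual mask")
    return WoundMask(mask, source="auto")


def load_manual_mask(path, target_frame: ChannelFrame) -> WoundMask:
    """Load a hand-drawn binary mask (PNG or TIFF, nonzero = wound)."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse RGB(A) to intensity
        arr = arr[..., :3].max(axis=-1)
    if arr.shape != target_frame.shape:
        raise MaskError(
            f"manual mask shape {arr.shape} does not match frame shape "
            f"{target_frame.shape}")
    mask = arr != 0
    if not mask.any():
        raise MaskError(f"manual mask {path} contains no wound pixels")
    return WoundMask(mask, source="manual")


def apply_mask(frame: ChannelFrame, mask: WoundMask) -> ChannelFrame:
    """Zero everything outside the wound; inside the wound unchanged."""
    mask.check_shape(frame.shape)
    return frame.with_pixels(np.where(mask.mask, frame.pixels, 0.0))


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Overlap 2|A∩B| / (|A|+|B|) between two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise MaskError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def cryo_foreground_mask(background_masks) -> WoundMask:
    """Default cryo wound mask: voxels that are background in no channel.

    Biopsies are whole-wound excisions, so after background zeroing every
    remaining voxel belongs to the wound tissue.
    """
    fg = None
    for bg in background_masks:
        fg = ~np.asarray(bg, bool) if fg is None else fg & ~np.asarray(bg, bool)
    if fg is None or not fg.any():
        raise SegmentationError("no foreground voxels remain after zeroing")
    return WoundMask(fg, source="auto")
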