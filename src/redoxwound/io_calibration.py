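"""TIFF I/O, manifest handling, and the two calibration procedures.

In-vivo frames are normalized to the day's cuvette reference intensity,
which cancels day-to-day excitation-lamp drift (the same multiplicative
factor hits the tissue and the cuvette frame).  Cryo stacks are flat-field
corrected slice-wise and low-intensity background voxels are zeroed.

Raw frames travel as 16-bit grayscale TIFF (values <= 16383); calibrated
outputs are written as 32-bit float TIFF.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd
import tifffile

from .errors import CalibrationError, FormatError, ManifestError
from .frames import ChannelFrame, CryoStack, CuvetteReference, MAX_DN

MANIFEST_COLUMNS = ["subject", "group", "day", "channel", "kind", "path"]
#: fraction of saturated wound pixels above which a warning is emitted
SATURATION_WARN_FRACTION = 0.01


# ---- TIFF I/O --------------------------------------------------------------

def write_tiff(path, array: np.ndarray) -> Path:
    """Write a frame (2D) or stack (3D, multi-page) as grayscale TIFF.

    Integer-valued data within the 14-bit range is stored as uint16;
    anything else (calibrated/dimensionless data) as float32.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(array)
    if (np.issubdtype(arr.dtype, np.integer)
            or (np.all(arr == np.rint(arr)) and arr.size and 0 <= arr.min() and arr.max() <= MAX_DN)):
        out = arr.astype(np.uint16)
    else:
        out = arr.astype(np.float32)
    tifffile.imwrite(path, out, photometric="minisblack")
    return path


def read_tiff(path) -> np.ndarray:
    """Read a grayscale TIFF frame or multi-page stack as float64."""
    arr = tifffile.imread(Path(path))
    if arr.ndim not in (2, 3):
        raise FormatError(f"{path}: expected 2D frame or 3D stack, got ndim={arr.ndim}")
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:2]):
        raise FormatError(f"{path}: RGB(A) images are not grayscale frames")
    if np.issubdtype(arr.dtype, np.integer) and arr.max(initial=0) > MAX_DN:
        raise FormatError(f"{path}: intensities exceed the 14-bit range")
    return arr.astype(np.float64)


# ---- manifest --------------------------------------------------------------

def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject": str, "group": str, "channel": str,
                                  "kind": str, "path": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest {path} lacks columns: {missing}")
    df["day"] = df["day"].astype(int)
    df.attrs["root"] = path.parent
    return df


def load_session(manifest: pd.DataFrame, subject: str, day: int,
                 root=None) -> Tuple[Dict[str, ChannelFrame], Dict[str, CuvetteReference]]:
    """Load one in-vivo session's three frames plus the day's cuvette references."""
    root = Path(root) if root is not None else Path(manifest.attrs.get("root", "."))
    sess = manifest[(manifest["subject"] == subject)
                    & (manifest["day"] == day) & (manifest["kind"] == "frame")]
    frames: Dict[str, ChannelFrame] = {}
    for ch in ("WHITE", "NADH", "FAD"):
        rows = sess[sess["channel"] == ch]
        if len(rows) != 1:
            raise ManifestError(
                f"session {subject}/day{day}: expected exactly one {ch} frame, "
                f"found {len(rows)}")
        row = rows.iloc[0]
        pixels = read_tiff(root / row["path"])
        if pixels.ndim != 2:
            raise FormatError(f"{row['path']}: session frames must be 2D")
        frames[ch] = ChannelFrame(pixels, ch, pixel_size_um=40.0,
                                  subject=subject, group=row["group"], day=day)
    refs: Dict[str, CuvetteReference] = {}
    cuv = manifest[(manifest["kind"] == "cuvette") & (manifest["day"] == day)]
    for ch in ("NADH", "FAD"):
        rows = cuv[cuv["channel"] == ch]
        if len(rows) != 1:
            raise ManifestError(
                f"day {day}: expected exactly one {ch} cuvette frame, found {len(rows)}")
        pixels = read_tiff(root / rows.iloc[0]["path"])
        # full-frame arithmetic mean: the reference solution is homogeneous
        refs[ch] = CuvetteReference(ch, float(pixels.mean()), day=day)
    return frames, refs


def load_cryo(manifest: pd.DataFrame, subject: str, day: int,
              root=None, voxel_size_um=(50.0, 40.0, 40.0)) -> Dict[str, CryoStack]:
    """Load one biopsy's per-channel stacks with their flat-field frames."""
    root = Path(root) if root is not None else Path(manifest.attrs.get("root", "."))
    sel = manifest[(manifest["subject"] == subject) & (manifest["day"] == day)]
    stacks: Dict[str, CryoStack] = {}
    for ch in ("NADH", "FAD"):
        srows = sel[(sel["channel"] == ch) & (sel["kind"] == "stack")]
        frows = sel[(sel["channel"] == ch) & (sel["kind"] == "flat")]
        if len(srows) != 1 or len(frows) != 1:
            raise ManifestError(
                f"biopsy {subject}/day{day}: need one {ch} stack and one flat, "
                f"found {len(srows)}/{len(frows)}")
        vox = read_tiff(root / srows.iloc[0]["path"])
        if vox.ndim != 3:
            raise FormatError(f"{srows.iloc[0]['path']}: cryo stacks must be 3D")
        flat = read_tiff(root / frows.iloc[0]["path"])
        stacks[ch] = CryoStack(vox, ch, voxel_size_um, flat,
                               subject=subject, group=srows.iloc[0]["group"], day=day)
    return stacks


# ---- calibration -----------------------------------------------------------

def calibrate_frame(frame: ChannelFrame, ref: CuvetteReference) -> ChannelFrame:
    """Normalize a fluorescence frame to the day's cuvette mean intensity.

    Output is dimensionless and flagged ``calibrated``; calibrating an
    already-calibrated frame is a contract violation, not an idempotent
    no-op, because the cuvette units would be applied twice.
    """
    if frame.calibrated:
        raise CalibrationError("frame is already calibrated")
    if frame.channel != ref.channel:
        raise CalibrationError(
            f"channel mismatch: frame {frame.channel} vs reference {ref.channel}")
    if not ref.mean_intensity > 0:
        raise CalibrationError("cuvette reference mean must be positive")
    saturated = np.count_nonzero(frame.pixels >= MAX_DN)
    if saturated > SATURATION_WARN_FRACTION * frame.pixels.size:
        warnings.warn(
            f"{frame.channel} frame has {saturated} saturated pixels "
            f"({100 * saturated / frame.pixels.size:.1f}%)", stacklevel=2)
    return frame.with_pixels(frame.pixels / ref.mean_intensity, calibrated=True)


def flat_field_correct(stack: CryoStack) -> CryoStack:
    """Divide every slice by the mean-normalized flat-field pattern."""
    if stack.corrected:
        raise CalibrationError("stack is already flat-field corrected")
    flat = stack.flat_field
    if np.any(flat <= 0):
        raise CalibrationError("flat field must be strictly positive everywhere")
    divisor = flat / flat.mean()
    out = CryoStack(stack.voxels / divisor[None, :, :], stack.channel,
                    stack.voxel_size_um, flat, subject=stack.subject,
                    group=stack.group, day=stack.day, corrected=True)
    return out


def zero_background(stack: CryoStack, threshold_fraction: float = 0.10
                    ) -> Tuple[CryoStack, np.ndarray]:
    """Zero voxels below a fraction of the stack's 99.5th-percentile intensity.

    The percentile anchor (rather than the maximum) resists hot pixels.
    Returns the zeroed stack and the boolean background mask; background
    voxels are excluded from all downstream redox statistics.
    """
    if not 0 <= threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in [0, 1)")
    cutoff = threshold_fraction * np.percentile(stack.voxels, 99.5)
    background = stack.voxels < cutoff
    vox = np.where(background, 0.0, stack.voxels)
    out = CryoStack(vox, stack.channel, stack.voxel_size_um, stack.flat_field,
                    subject=stack.subject, group=stack.group, day=stack.day,
                    corrected=stack.corrected)
    return out, background
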