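"""In-memory containers for frames, stacks, masks and redox maps.

Intensities are kept as float64 throughout; raw camera frames hold integer
digital numbers (DN) in [0, 2^14 - 1], calibrated frames are dimensionless.
All grids are 0-based, row-major, pixel/voxel-centred.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import MaskError

#: valid acquisition channels
CHANNELS = ("WHITE", "NADH", "FAD")
#: camera bit depth is fixed by the instrument (14-bit EMCCD)
BIT_DEPTH = 14
MAX_DN = 2**BIT_DEPTH - 1


@dataclass
class ChannelFrame:
    """One 2D grayscale acquisition in a single optical channel."""

    pixels: np.ndarray
    channel: str
    pixel_size_um: float
    subject: Optional[str] = None
    group: Optional[str] = None
    day: Optional[int] = None
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"frame must be 2D, got shape {self.pixels.shape}")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")
        if not self.calibrated and np.any(self.pixels > MAX_DN):
            raise ValueError(f"raw frame exceeds {MAX_DN} DN")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, *, calibrated: Optional[bool] = None) -> "ChannelFrame":
        out = replace(self, pixels=pixels)
        if calibrated is not None:
            out.calibrated = calibrated
        return out


@dataclass
class CuvetteReference:
    """Mean intensity of a reference-fluorophore cuvette frame for one channel."""

    channel: str
    mean_intensity: float
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.channel not in ("NADH", "FAD"):
            raise ValueError("cuvette references exist only for NADH/FAD")
        if not self.mean_intensity > 0:
            raise ValueError("cuvette mean intensity must be positive")


@dataclass
class CryoStack:
    """One 3D per-channel intensity volume with its flat-field reference.

    ``voxels`` is (z, y, x); ``flat_field`` is a strictly positive (y, x)
    illumination pattern shared by every slice.
    """

    voxels: np.ndarray
    channel: str
    voxel_size_um: tuple
    flat_field: np.ndarray
    subject: Optional[str] = None
    group: Optional[str] = None
    day: Optional[int] = None
    corrected: bool = False

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        self.flat_field = np.asarray(self.flat_field, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("stack must be 3D (z, y, x)")
        if self.flat_field.shape != self.voxels.shape[1:]:
            raise ValueError("flat field shape must match slice shape")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.voxels.shape


@dataclass
class WoundMask:
    """Binary wound region aligned to its source frame or stack."""

    mask: np.ndarray
    source: str = "auto"  # auto | manual | truth

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.source not in ("auto", "manual", "truth"):
            raise ValueError(f"unknown mask source {self.source!r}")

    @property
    def n_pixels(self) -> int:
        # recounted on access so the invariant cannot go stale
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple:
        return self.mask.shape

    def check_shape(self, other_shape: tuple) -> None:
        if self.mask.shape != tuple(other_shape):
            raise MaskError(
                f"mask shape {self.mask.shape} does not match frame shape {tuple(other_shape)}"
            )


@dataclass
class RedoxMap:
    """Pixel/voxel-wise NADH/FAD ratio field, NaN outside the valid set."""

    values: np.ndarray
    valid_mask: np.ndarray
    n_mask: int
    excluded_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask shapes differ")
        defined = self.values[self.valid_mask]
        if defined.size and (np.any(~np.isfinite(defined)) or np.any(defined < 0)):
            raise ValueError("defined ratios must be finite and non-negative")

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def defined_values(self) -> np.ndarray:
        return self.values[self.valid_mask]


@dataclass
class SurfaceMetrics:
    """Surface redox ratio and wound-area quantities for one in-vivo session."""

    surface_rr: float
    n_pixels: int
    n_valid: int
    normalized_area: Optional[float] = None
    subject: Optional[str] = None
    group: Optional[str] = None
    day: Optional[int] = None


@dataclass
class VolumetricMetrics:
    """Volumetric redox ratio for one cryo-imaged biopsy."""

    volumetric_rr: float
    n_voxels: int
    subject: Optional[str] = None
    group: Optional[str] = None
    day: Optional[int] = None


@dataclass
class Histogram:
    """Ratio histogram with explicit under/overflow bins.

    ``counts``/``fractions`` have length n_bins + 2: index 0 is underflow,
    index -1 overflow, the rest the in-range bins bounded by ``edges``.
    """

    edges: np.ndarray
    counts: np.ndarray
    fractions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.fractions is None:
            total = self.counts.sum()
            self.fractions = self.counts / total if total else self.counts.astype(float)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])
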