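"""Shared image containers used across the pipeline.

Axial CT slices are carried as plain 2-D NumPy arrays wrapped in small
dataclasses that keep track of the physical pixel spacing and, after
resizing, of the native acquisition size — both are needed to convert
pixel counts back into physical areas (mm^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Tissue label codes used throughout: background, skeletal muscle (SM),
#: subcutaneous adipose tissue (SAT), visceral adipose tissue (VAT), other.
BACKGROUND, SM, SAT, VAT, OTHER = 0, 1, 2, 3, 4
CLASS_NAMES = {BACKGROUND: "background", SM: "SM", SAT: "SAT", VAT: "VAT", OTHER: "other"}
N_CLASSES = 5


@dataclass
class RawSlice:
    """A single axial CT slice in calibrated Hounsfield units."""

    hu: np.ndarray
    pixel_spacing_mm: float

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu)
        if self.hu.ndim != 2 or self.hu.shape[0] != self.hu.shape[1]:
            raise ValueError(f"expected a square 2-D HU array, got shape {self.hu.shape}")
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("HU array contains non-finite values")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")

    @property
    def size(self) -> int:
        return self.hu.shape[0]


@dataclass
class NormalizedImage:
    """An intensity image in [0, 1] with provenance of its native size.

    ``pixel_spacing_mm`` always refers to the *native* resolution; the
    spacing at the current resolution is ``pixel_spacing_mm * resize_factor``.
    """

    intensity: np.ndarray
    native_size: int
    current_size: int
    pixel_spacing_mm: float

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.current_size, self.current_size):
            raise ValueError("intensity shape inconsistent with current_size")
        if self.native_size < self.current_size:
            raise ValueError("native_size must be >= current_size")
        lo, hi = float(self.intensity.min(initial=0.0)), float(self.intensity.max(initial=0.0))
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"intensities outside [0, 1]: [{lo}, {hi}]")

    @property
    def resize_factor(self) -> float:
        return self.native_size / self.current_size


@dataclass
class SegmentationMask:
    """Per-pixel tissue codes 0–4 with spacing/resize bookkeeping."""

    codes: np.ndarray
    pixel_spacing_mm: float
    native_size: int = 0
    current_size: int = 0

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2 or self.codes.shape[0] != self.codes.shape[1]:
            raise ValueError(f"expected a square 2-D mask, got shape {self.codes.shape}")
        side = self.codes.shape[0]
        if self.current_size == 0:
            self.current_size = side
        if self.native_size == 0:
            self.native_size = side
        if self.codes.shape != (self.current_size, self.current_size):
            raise ValueError("codes shape inconsistent with current_size")
        labels = np.unique(self.codes)
        if labels.min(initial=0) < 0 or labels.max(initial=0) >= N_CLASSES:
            raise ValueError(f"mask labels outside 0..{N_CLASSES - 1}: {labels}")

    @property
    def resize_factor(self) -> float:
        return self.native_size / self.current_size

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.codes.ravel().astype(np.int64), minlength=N_CLASSES)

    def copy_with(self, **kw) -> "SegmentationMask":
        return replace(self, **kw)
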