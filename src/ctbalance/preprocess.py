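"""CT preprocessing: HU windowing, histogram stretching, resizing.

The preprocessing chain applied before training is
``window -> stretch -> resize``: clip Hounsfield units to a soft-tissue
window ([-190, 150] by default, which spans muscle, fat and the lower edge
of bone), linearly stretch percentile endpoints to [0, 1], and resample to
the network input size (bilinear for images, nearest-neighbour for label
masks so the categorical codes survive).
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as _sk_resize

from .types import NormalizedImage, RawSlice, SegmentationMask

HU_WINDOW = (-190.0, 150.0)
STRETCH_PERCENTILES = (1.0, 99.0)


def apply_hu_window(sl: RawSlice, lo: float = HU_WINDOW[0], hi: float = HU_WINDOW[1]) -> RawSlice:
    """Clip (saturate) HU values to ``[lo, hi]``. Idempotent."""
    if not lo < hi:
        raise ValueError(f"window requires lo < hi, got [{lo}, {hi}]")
    return RawSlice(np.clip(sl.hu, lo, hi), sl.pixel_spacing_mm)


def volume_percentile_bounds(slices, p_lo: float = STRETCH_PERCENTILES[0],
                             p_hi: float = STRETCH_PERCENTILES[1]) -> tuple:
    """Stretch endpoints pooled over a whole volume, for per-volume
    (rather than per-slice) normalization."""
    pooled = np.concatenate([np.asarray(s, dtype=float).ravel() for s in slices])
    lo, hi = np.percentile(pooled, [p_lo, p_hi])
    return float(lo), float(hi)


def histogram_stretch(sl: RawSlice, p_lo: float = STRETCH_PERCENTILES[0],
                      p_hi: float = STRETCH_PERCENTILES[1],
                      bounds: tuple | None = None) -> NormalizedImage:
    """Linearly map the (p_lo, p_hi) percentiles to 0 and 1, clipping tails.

    Percentiles are computed per slice unless explicit ``bounds`` (e.g.
    from :func:`volume_percentile_bounds`) are given. A constant slice has
    no dynamic range and maps to all-zeros.
    """
    if not p_lo < p_hi:
        raise ValueError("p_lo must be < p_hi")
    hu = np.asarray(sl.hu, dtype=float)
    lo, hi = bounds if bounds is not None else np.percentile(hu, [p_lo, p_hi])
    if hi <= lo:
        out = np.zeros_like(hu)
    else:
        out = np.clip((hu - lo) / (hi - lo), 0.0, 1.0)
    size = hu.shape[0]
    return NormalizedImage(out, native_size=size, current_size=size,
                           pixel_spacing_mm=sl.pixel_spacing_mm)


def resize_image(img: NormalizedImage, target: int = 256) -> NormalizedImage:
    """Bilinear resample to ``target`` per side (downsampling only)."""
    if target > img.native_size:
        raise ValueError(f"target {target} exceeds native size {img.native_size}")
    if target == img.current_size:
        return img
    out = _sk_resize(img.intensity, (target, target), order=1,
                     anti_aliasing=False, preserve_range=True)
    return NormalizedImage(np.clip(out, 0.0, 1.0), native_size=img.native_size,
                           current_size=target, pixel_spacing_mm=img.pixel_spacing_mm)


def resize_mask(mask: SegmentationMask, target: int) -> SegmentationMask:
    """Nearest-neighbour resample: the label set can only shrink, never grow."""
    if target > mask.native_size:
        raise ValueError(f"target {target} exceeds native size {mask.native_size}")
    if target == mask.current_size:
        return mask
    out = _sk_resize(mask.codes, (target, target), order=0,
                     anti_aliasing=False, preserve_range=True).astype(mask.codes.dtype)
    return SegmentationMask(out, mask.pixel_spacing_mm,
                            native_size=mask.native_size, current_size=target)


def preprocess_slice(
    hu: np.ndarray,
    pixel_spacing_mm: float,
    target_size: int,
    window: tuple = HU_WINDOW,
    percentiles: tuple = STRETCH_PERCENTILES,
) -> NormalizedImage:
    """Full deterministic chain window -> stretch -> resize for one slice."""
    sl = RawSlice(np.asarray(hu, dtype=float), pixel_spacing_mm)
    sl = apply_hu_window(sl, *window)
    img = histogram_stretch(sl, *percentiles)
    return resize_image(img, target_size)
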