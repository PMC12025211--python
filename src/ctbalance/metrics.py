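"""Evaluation battery for detection and segmentation.

Slice-level: signed/absolute L3 slice error and Bland–Altman agreement.
Pixel-level: one-vs-rest confusion counts per class, Jaccard, Dice,
sensitivity, specificity, mean surface distance (MSD, in mm), physical
tissue areas with the resize correction factor ``(native/current)^2``,
and ordinary-least-squares R^2 between predicted and reference areas.

Conventions for degenerate cases (never met on real cohorts, but phantom
folds can produce them): an empty-vs-empty class scores 1 on the overlap
metrics, and MSD is reported as missing (NaN) when a boundary is empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .types import N_CLASSES

#: 4-connected structuring element for boundary extraction.
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class ConfusionCounts:
    """One-vs-rest TP/FP/FN/TN per class (arrays of length n_classes)."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    def __post_init__(self) -> None:
        for a in (self.tp, self.fp, self.fn, self.tn):
            if np.any(np.asarray(a) < 0):
                raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> np.ndarray:
        return self.tp + self.fp + self.fn + self.tn

    def per_class(self, k: int) -> "ConfusionCounts":
        return ConfusionCounts(*(np.atleast_1d(a[k]) for a in (self.tp, self.fp, self.fn, self.tn)))


def confusion(predicted, true, n_classes: int = N_CLASSES) -> ConfusionCounts:
    """One-vs-rest confusion counts from label arrays of identical shape."""
    p = np.asarray(predicted).ravel()
    t = np.asarray(true).ravel()
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {np.asarray(predicted).shape} vs {np.asarray(true).shape}")
    if p.size and (min(p.min(), t.min()) < 0 or max(p.max(), t.max()) >= n_classes):
        raise ValueError("labels outside 0..n_classes-1")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    tp = np.diag(cm).copy()
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def _safe_ratio(num, den):
    """Elementwise num/den with the 0/0 -> 1 empty-class convention."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.ones_like(num)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def jaccard(c: ConfusionCounts) -> np.ndarray:
    """TP / (TP + FP + FN); empty-vs-empty -> 1."""
    return _safe_ratio(c.tp, c.tp + c.fp + c.fn)


def dice(c: ConfusionCounts) -> np.ndarray:
    """2 TP / (2 TP + FP + FN); empty-vs-empty -> 1."""
    return _safe_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)


def sensitivity(c: ConfusionCounts) -> np.ndarray:
    """Recall, TP / (TP + FN)."""
    return _safe_ratio(c.tp, c.tp + c.fn)


def specificity(c: ConfusionCounts) -> np.ndarray:
    """TN / (TN + FP)."""
    return _safe_ratio(c.tn, c.tn + c.fp)


def precision(c: ConfusionCounts) -> np.ndarray:
    """TP / (TP + FP)."""
    return _safe_ratio(c.tp, c.tp + c.fp)


def f1_score(c: ConfusionCounts) -> np.ndarray:
    return dice(c)  # F1 over counts is the Dice coefficient


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Mask pixels with at least one 4-connected neighbour outside the mask
    (image-border neighbours count as outside)."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return np.zeros_like(m)
    interior = ndimage.binary_erosion(m, structure=_CROSS, border_value=0)
    return m & ~interior


def mean_surface_distance(pred_mask, true_mask, pixel_spacing_mm: float,
                          mode: str = "directed") -> float:
    """Average distance (mm) from the predicted boundary to the nearest
    true-boundary point; ``mode='symmetric'`` averages both directions.

    ``pixel_spacing_mm`` must be the spacing at the masks' current
    resolution (native spacing times the resize factor). Returns NaN if
    either boundary is empty.
    """
    if mode not in ("directed", "symmetric"):
        raise ValueError(f"unknown mode {mode!r}")
    pb = boundary_pixels(pred_mask)
    tb = boundary_pixels(true_mask)
    if not pb.any() or not tb.any():
        return float("nan")
    # Distance (pixels) to the nearest true-boundary pixel, everywhere.
    d_to_true = ndimage.distance_transform_edt(~tb)
    fwd = float(d_to_true[pb].mean())
    if mode == "directed":
        return fwd * pixel_spacing_mm
    d_to_pred = ndimage.distance_transform_edt(~pb)
    bwd = float(d_to_pred[tb].mean())
    return 0.5 * (fwd + bwd) * pixel_spacing_mm


def slice_error(predicted_index: int, true_index: int) -> int:
    """Signed slice-position difference, predicted - true."""
    return int(predicted_index) - int(true_index)


def abs_slice_error(predicted_index: int, true_index: int) -> int:
    return abs(slice_error(predicted_index, true_index))


@dataclass
class BlandAltmanSummary:
    mean_difference: float
    sd_difference: float
    lower_limit: float
    upper_limit: float
    fraction_within: float
    n: int


def bland_altman(pairs) -> BlandAltmanSummary:
    """Limits-of-agreement analysis on (predicted, true) pairs.

    Differences are predicted - true; limits are mean ± 1.96 times the
    sample SD (n-1 denominator); the within-limits fraction uses strict
    inequalities, so it is 0 in the degenerate all-equal case.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 (predicted, true) pairs")
    diffs = arr[:, 0] - arr[:, 1]
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    lower, upper = mean - 1.96 * sd, mean + 1.96 * sd
    within = float(np.mean((diffs > lower) & (diffs < upper)))
    return BlandAltmanSummary(mean, sd, lower, upper, within, len(diffs))


def tissue_area(mask, cls: int, native_pixel_spacing_mm: float,
                native_size: int, current_size: int) -> float:
    """Physical class area in mm^2: pixel count x spacing^2 x (native/current)^2.

    The squared resize ratio restores the native field of view (a factor of
    exactly 4 for a 512 -> 256 resize).
    """
    if native_pixel_spacing_mm <= 0:
        raise ValueError("pixel spacing must be positive")
    count = int(np.sum(np.asarray(mask) == cls))
    factor = (native_size / current_size) ** 2
    return count * native_pixel_spacing_mm**2 * factor


def r_squared(predicted, reference) -> float:
    """Ordinary least-squares coefficient of determination (offset-invariant)."""
    x = np.asarray(reference, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 pairs")
    if np.ptp(x) == 0:
        raise ValueError("reference values have zero variance")
    if np.ptp(y) == 0:
        # A constant prediction explains none of the reference variance.
        return 0.0
    res = stats.linregress(x, y)
    return float(res.rvalue**2)


@dataclass
class SegMetrics:
    """Per-class and macro-averaged segmentation scores."""

    classes: list
    jaccard: np.ndarray
    dice: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    msd_mm: np.ndarray

    def macro(self, name: str) -> float:
        vals = getattr(self, name)
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if vals.size else float("nan")

    def as_rows(self) -> list:
        from .types import CLASS_NAMES

        rows = []
        for i, k in enumerate(self.classes):
            rows.append(dict(tissue=CLASS_NAMES.get(k, str(k)),
                             jaccard=float(self.jaccard[i]), dice=float(self.dice[i]),
                             sensitivity=float(self.sensitivity[i]),
                             specificity=float(self.specificity[i]),
                             msd_mm=float(self.msd_mm[i])))
        return rows


def segmentation_metrics(pred_codes, true_codes, pixel_spacing_mm_current: float,
                         classes=(1, 2, 3, 4), msd_mode: str = "directed") -> SegMetrics:
    """Full per-class score table for one predicted/reference mask pair."""
    c = confusion(pred_codes, true_codes, n_classes=N_CLASSES)
    classes = list(classes)
    idx = np.asarray(classes)
    msd = np.array([
        mean_surface_distance(np.asarray(pred_codes) == k, np.asarray(true_codes) == k,
                              pixel_spacing_mm_current, mode=msd_mode)
        for k in classes
    ])
    return SegMetrics(classes, jaccard(c)[idx], dice(c)[idx],
                      sensitivity(c)[idx], specificity(c)[idx], msd)
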