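"""Correction design variables (CDVs) for class-imbalance mitigation.

The strategy treats two imbalance-correction knobs as optimizable design
variables alongside the usual training hyperparameters:

* ``d_a`` — the augmentation ratio: the minority class is oversampled (via
  rotation / horizontal flip / vertical flip of existing minority samples)
  until its count reaches ``round(d_a * n_majority)``, with ``d_a <= 1``
  (exact 1:1 balance as the upper bound). Used by the detection task only.
* ``d_c`` — per-class weight multipliers for a cost-sensitive weighted
  cross-entropy loss, each bounded below by a task-specific minimum:
  ``1/sqrt(f_k)`` for detection (class frequency ``f_k``), and the class
  pixel ratio ``f_k`` for segmentation.

The full design vector is ``d = {d_h, d_a, d_c}`` where ``d_h`` are the six
trainer hyperparameters searched over the ranges in
:data:`HYPERPARAMETER_BOUNDS`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: (lower, upper, kind) per trainer hyperparameter.
HYPERPARAMETER_BOUNDS = {
    "l2_regularization": (1e-4, 1e-2, "log_continuous"),
    "learning_rate": (1e-4, 1e-2, "log_continuous"),
    "batch_size": (10, 32, "integer"),
    "gradient_threshold": (1, 6, "integer"),
    "epochs": (5, 20, "integer"),
    "momentum": (0.7, 0.99, "continuous"),
}

TRANSFORMS = ("rotation", "hflip", "vflip")
DEFAULT_ROTATION_RANGE_DEG = 15.0


@dataclass
class Hyperparameters:
    l2_regularization: float = 1e-3
    learning_rate: float = 1e-3
    batch_size: int = 21
    gradient_threshold: int = 3
    epochs: int = 12
    momentum: float = 0.85

    def validate(self) -> None:
        for name, (lo, hi, kind) in HYPERPARAMETER_BOUNDS.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
            if kind == "integer" and int(v) != v:
                raise ValueError(f"{name} must be an integer, got {v}")

    @classmethod
    def midrange(cls) -> "Hyperparameters":
        """Mid-range defaults (geometric midpoint on log-scaled axes)."""
        vals = {}
        for name, (lo, hi, kind) in HYPERPARAMETER_BOUNDS.items():
            if kind == "log_continuous":
                vals[name] = float(np.sqrt(lo * hi))
            elif kind == "integer":
                vals[name] = int(round((lo + hi) / 2))
            else:
                vals[name] = (lo + hi) / 2
        return cls(**vals)


@dataclass
class DesignVector:
    """d = {d_h, d_a, d_c}: hyperparameters, augmentation ratio, class weights."""

    d_h: Hyperparameters
    d_a: float | None = None  # detection task only
    d_c: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.d_h.validate()
        if self.d_a is not None and not (0.0 < self.d_a <= 1.0):
            raise ValueError(f"d_a must lie in (0, 1], got {self.d_a}")
        if self.d_c is not None:
            self.d_c = np.asarray(self.d_c, dtype=float)
            if np.any(self.d_c <= 0) or not np.all(np.isfinite(self.d_c)):
                raise ValueError("d_c entries must be finite and positive")

    def to_dict(self) -> dict:
        return {
            "d_h": dataclasses.asdict(self.d_h),
            "d_a": self.d_a,
            "d_c": None if self.d_c is None else list(map(float, self.d_c)),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "DesignVector":
        return cls(Hyperparameters(**d["d_h"]), d.get("d_a"),
                   None if d.get("d_c") is None else np.asarray(d["d_c"], dtype=float))


@dataclass
class AugmentationPlan:
    """Deterministic recipe raising the minority count to
    ``round(d_a * n_majority)`` via seeded transforms of existing samples."""

    n_minority: int
    n_majority: int
    target_minority: int
    n_augmented_needed: int
    op_sequence: list  # (minority source position, transform name, transform seed)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def make_augmentation_plan(n_minority: int, n_majority: int, d_a: float, seed: int) -> AugmentationPlan:
    if not (0.0 < d_a <= 1.0):
        raise ValueError(f"augmentation ratio d_a must lie in (0, 1], got {d_a}")
    target = int(round(d_a * n_majority))
    n_needed = max(0, target - n_minority)
    rng = np.random.default_rng(seed)
    ops = []
    for i in range(n_needed):
        src = i % n_minority  # cycle through minority samples
        tf = TRANSFORMS[int(rng.integers(len(TRANSFORMS)))]
        ops.append((src, tf, int(rng.integers(0, 2**31 - 1))))
    return AugmentationPlan(n_minority, n_majority, target, n_needed, ops)


def augment_arrays(
    image: np.ndarray,
    mask: np.ndarray | None,
    transform: str,
    transform_seed: int,
    rotation_range_deg: float = DEFAULT_ROTATION_RANGE_DEG,
) -> tuple:
    """Apply one geometric transform to an image (and its mask, jointly).

    Flips are exact index reversals; rotation draws its angle uniformly
    from ±``rotation_range_deg`` using ``transform_seed`` (bilinear for the
    image, nearest for the mask, zero fill outside the canvas).
    """
    if transform == "hflip":
        img = image[:, ::-1].copy()
        msk = None if mask is None else mask[:, ::-1].copy()
    elif transform == "vflip":
        img = image[::-1, :].copy()
        msk = None if mask is None else mask[::-1, :].copy()
    elif transform == "rotation":
        rng = np.random.default_rng(transform_seed)
        angle = float(rng.uniform(-rotation_range_deg, rotation_range_deg))
        img = ndimage.rotate(image, angle, reshape=False, order=1, mode="constant", cval=0.0)
        img = np.clip(img, 0.0, 1.0)
        msk = None
        if mask is not None:
            msk = ndimage.rotate(mask, angle, reshape=False, order=0,
                                 mode="constant", cval=0).astype(mask.dtype)
    else:
        raise ValueError(f"unknown transform {transform!r}; expected one of {TRANSFORMS}")
    return img, msk


def augment_image(img, transform: str, transform_seed: int, mask=None,
                  rotation_range_deg: float = DEFAULT_ROTATION_RANGE_DEG):
    """Typed wrapper over :func:`augment_arrays` for NormalizedImage/SegmentationMask."""
    from .types import NormalizedImage, SegmentationMask

    a, m = augment_arrays(img.intensity, None if mask is None else mask.codes,
                          transform, transform_seed, rotation_range_deg)
    out_img = NormalizedImage(a, img.native_size, img.current_size, img.pixel_spacing_mm)
    if mask is None:
        return out_img
    out_mask = SegmentationMask(m, mask.pixel_spacing_mm, mask.native_size, mask.current_size)
    return out_img, out_mask


def segmentation_augment(images: list, masks: list, factor: int = 4, seed: int = 0,
                         rotation_range_deg: float = DEFAULT_ROTATION_RANGE_DEG) -> tuple:
    """Grow a paired (image, mask) dataset to ``factor`` times its size.

    Originals are retained; the extras cycle through the originals applying
    seeded random transforms (image and mask transformed together).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    n = len(images)
    if n != len(masks):
        raise ValueError("images and masks must be paired")
    rng = np.random.default_rng(seed)
    out_imgs, out_masks = list(images), list(masks)
    for i in range(n * (factor - 1)):
        src = i % n
        tf = TRANSFORMS[int(rng.integers(len(TRANSFORMS)))]
        tseed = int(rng.integers(0, 2**31 - 1))
        a, m = augment_arrays(np.asarray(images[src]), np.asarray(masks[src]), tf, tseed,
                              rotation_range_deg)
        out_imgs.append(a)
        out_masks.append(m)
    return out_imgs, out_masks


@dataclass
class ClassWeightVector:
    """Per-class loss weights with their lower-bound constraints.

    ``weights`` are normalized to mean 1 (so loss magnitudes stay
    comparable across candidate d_c during optimization); ``minima`` are
    stored pre-normalization.
    """

    weights: np.ndarray
    minima: np.ndarray
    task: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.minima = np.asarray(self.minima, dtype=float)
        if np.any(~np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise ValueError("class weights must be finite and positive")

    def to_json(self) -> str:
        return json.dumps({"weights": self.weights.tolist(),
                           "minima": self.minima.tolist(), "task": self.task})

    @classmethod
    def from_json(cls, text: str) -> "ClassWeightVector":
        d = json.loads(text)
        return cls(np.asarray(d["weights"]), np.asarray(d["minima"]), d["task"])


def class_weight_minima(class_frequencies: np.ndarray, task: str,
                        min_rule: str = "pixel_ratio") -> np.ndarray:
    """Lower bounds for the class-weight design variables.

    detection: ``1/sqrt(f_k)`` (inverse-square-root frequency);
    segmentation: the class pixel ratio ``f_k`` by default
    (``min_rule='inverse_pixel_ratio'`` switches to ``1/f_k``).
    """
    f = np.asarray(class_frequencies, dtype=float)
    if np.any(f <= 0):
        bad = int(np.argmin(f))
        raise ValueError(f"class {bad} has zero (or negative) frequency")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1, got {f.sum()}")
    if task == "detection":
        return 1.0 / np.sqrt(f)
    if task == "segmentation":
        if min_rule == "pixel_ratio":
            return f.copy()
        if min_rule == "inverse_pixel_ratio":
            return 1.0 / f
        raise ValueError(f"unknown min_rule {min_rule!r}")
    raise ValueError(f"unknown task {task!r}")


def compute_class_weights(class_frequencies, d_c, task: str,
                          min_rule: str = "pixel_ratio") -> ClassWeightVector:
    """Clamp candidate multipliers ``d_c`` at the task minima, then rescale
    to mean 1."""
    minima = class_weight_minima(class_frequencies, task, min_rule)
    d_c = np.asarray(d_c, dtype=float)
    if d_c.shape != minima.shape:
        raise ValueError(f"d_c has {d_c.shape[0]} entries for {minima.shape[0]} classes")
    raw = np.maximum(minima, d_c)
    weights = raw / raw.mean()
    return ClassWeightVector(weights=weights, minima=minima, task=task)


def weighted_cross_entropy(probabilities: np.ndarray, labels: np.ndarray,
                           weights) -> float:
    """Mean of ``-w_y * log p_y`` over samples (or pixels).

    ``probabilities`` has one row per item, rows summing to 1; reduces to
    plain cross-entropy when all weights are 1.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    w = weights.weights if isinstance(weights, ClassWeightVector) else np.asarray(weights, dtype=float)
    if p.ndim != 2 or y.shape != (p.shape[0],):
        raise ValueError(f"shape mismatch: probabilities {p.shape}, labels {y.shape}")
    if np.any((y < 0) | (y >= p.shape[1])):
        raise ValueError("labels outside the class range")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    p_true = np.clip(p[np.arange(len(y)), y], 1e-12, None)
    return float(np.mean(-w[y] * np.log(p_true)))
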