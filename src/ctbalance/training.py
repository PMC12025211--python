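"""Task definitions, patient-level cross-validation and reference trainers.

Two learning tasks share one trainer contract:

* **detection** — binary classification of axial slices (L3 vs non-L3),
  with minority oversampling driven by the augmentation-ratio design
  variable and inverse-sqrt-frequency weight minima;
* **segmentation** — 5-class per-pixel tissue labelling of L3 slices only,
  with a fixed 4x dataset augmentation and pixel-ratio weight minima.

Cross-validation is patient-level: all slices of a patient share one fold,
so no patient ever appears in both a training and a test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .imbalance import (
    AugmentationPlan,
    ClassWeightVector,
    DesignVector,
    augment_arrays,
    make_augmentation_plan,
    segmentation_augment,
)
from .nn import SmallResNet, SmallUNet, predict_in_batches, sgdm_train
from .phantom import PatientVolume
from .preprocess import HU_WINDOW, STRETCH_PERCENTILES, preprocess_slice, resize_mask
from .types import N_CLASSES

DETECTION_INPUT_SIZE = 16
SEGMENTATION_INPUT_SIZE = 24


@dataclass
class FoldAssignment:
    """Patient-id -> fold-index partition with near-equal fold sizes."""

    k: int
    mapping: dict
    seed: int

    def patients_in_fold(self, fold: int) -> list:
        return sorted(p for p, f in self.mapping.items() if f == fold)

    def train_patients(self, test_fold: int) -> list:
        return sorted(p for p, f in self.mapping.items() if f != test_fold)

    def fold_sizes(self) -> list:
        return [len(self.patients_in_fold(i)) for i in range(self.k)]


def split_folds(cohort: list, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Deterministic shuffled round-robin split; fold sizes differ by <= 1."""
    if len(cohort) < k:
        raise ValueError(f"need at least k={k} patients, got {len(cohort)}")
    pids = [v.patient_id for v in cohort]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pids))
    mapping = {pids[j]: i % k for i, j in enumerate(order)}
    return FoldAssignment(k, mapping, seed)


def check_no_leakage(assignment: FoldAssignment) -> None:
    """Every patient in exactly one fold; folds partition the cohort."""
    folds = [set(assignment.patients_in_fold(i)) for i in range(assignment.k)]
    union = set().union(*folds)
    if len(union) != sum(len(f) for f in folds):
        raise RuntimeError("patient leakage: a patient appears in more than one fold")
    if union != set(assignment.mapping):
        raise RuntimeError("folds do not cover the cohort")


# ---------------------------------------------------------------------------
# Dataset construction
# ---------------------------------------------------------------------------

@dataclass
class PreprocessConfig:
    window: tuple = HU_WINDOW
    percentiles: tuple = STRETCH_PERCENTILES
    detection_size: int = DETECTION_INPUT_SIZE
    segmentation_size: int = SEGMENTATION_INPUT_SIZE


def _volumes(cohort: list, pids: list) -> list:
    by_id = {v.patient_id: v for v in cohort}
    return [by_id[p] for p in pids]


def detection_class_counts(cohort: list, train_pids: list) -> tuple:
    """(n_l3, n_non_l3) over the training patients."""
    vols = _volumes(cohort, train_pids)
    n_l3 = sum(int(v.l3_flags.sum()) for v in vols)
    n_tot = sum(v.n_slices for v in vols)
    return n_l3, n_tot - n_l3


def preprocess_volume(volume: PatientVolume, size: int, cfg: PreprocessConfig) -> np.ndarray:
    return np.stack([
        preprocess_slice(hu, volume.pixel_spacing_mm, size, cfg.window, cfg.percentiles).intensity
        for hu in volume.slices
    ]).astype(np.float32)


def build_detection_dataset(cohort: list, train_pids: list, plan: AugmentationPlan,
                            cfg: PreprocessConfig | None = None) -> tuple:
    """Preprocessed training set with the minority class raised exactly to
    the plan's ``target_minority``. Labels: 1 = L3 (minority), 0 = non-L3.

    The plan must have been built from these training patients; mismatched
    class counts are rejected as a leakage guard.
    """
    cfg = cfg or PreprocessConfig()
    vols = _volumes(cohort, train_pids)
    imgs, labels = [], []
    for v in vols:
        arr = preprocess_volume(v, cfg.detection_size, cfg)
        imgs.append(arr)
        labels.append(v.l3_flags.astype(np.intp))
    X = np.concatenate(imgs)
    y = np.concatenate(labels)
    n_min, n_maj = int(y.sum()), int((1 - y).sum())
    if (plan.n_minority, plan.n_majority) != (n_min, n_maj):
        raise ValueError(
            f"plan built for counts ({plan.n_minority}, {plan.n_majority}) "
            f"but training folds contain ({n_min}, {n_maj})"
        )
    minority_idx = np.flatnonzero(y == 1)
    extra = []
    for src, tf, tseed in plan.op_sequence:
        img, _ = augment_arrays(X[minority_idx[src]], None, tf, tseed)
        extra.append(img.astype(np.float32))
    if extra:
        X = np.concatenate([X, np.stack(extra)])
        y = np.concatenate([y, np.ones(len(extra), dtype=np.intp)])
    return X[:, None, :, :], y


def build_segmentation_dataset(cohort: list, train_pids: list, factor: int = 4,
                               seed: int = 0, cfg: PreprocessConfig | None = None) -> tuple:
    """(images, masks) from L3-flagged slices only, augmented ``factor`` x."""
    cfg = cfg or PreprocessConfig()
    size = cfg.segmentation_size
    imgs, msks = [], []
    for v in _volumes(cohort, train_pids):
        for i in v.l3_indices():
            if v.masks[i] is None:
                raise ValueError(f"missing mask on L3 slice {i} of {v.patient_id}")
            img = preprocess_slice(v.slices[i], v.pixel_spacing_mm, size,
                                   cfg.window, cfg.percentiles).intensity
            imgs.append(img.astype(np.float32))
            msks.append(resize_mask(v.masks[i], size).codes)
    imgs, msks = segmentation_augment(imgs, msks, factor=factor, seed=seed)
    X = np.stack([np.asarray(im, dtype=np.float32) for im in imgs])[:, None, :, :]
    M = np.stack([np.asarray(m, dtype=np.intp) for m in msks])
    return X, M


def segmentation_pixel_frequencies(masks: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    counts = np.bincount(np.asarray(masks).ravel().astype(np.int64), minlength=n_classes)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Trainer contract and reference backends
# ---------------------------------------------------------------------------

@dataclass
class TrainedModelHandle:
    model: object
    design: DesignVector
    metadata: dict = field(default_factory=dict)


class TrainerContract(Protocol):
    """Seedable trainer backend: same seed + same inputs => same predictions."""

    def fit(self, images: np.ndarray, labels: np.ndarray, design: DesignVector,
            weights: ClassWeightVector, seed: int) -> TrainedModelHandle: ...

    def predict_probabilities(self, handle: TrainedModelHandle,
                              images: np.ndarray) -> np.ndarray: ...


def _standardize_fit(images: np.ndarray) -> tuple:
    """Global intensity standardization statistics of a training set.

    Centring/scaling the [0, 1] intensities markedly accelerates SGDM
    convergence at the small step budgets searched here; the statistics
    are stored on the model handle and re-applied at prediction time.
    """
    mu = float(images.mean())
    sd = float(images.std())
    return mu, sd if sd > 0 else 1.0


class ReferenceDetector:
    """Small residual CNN satisfying :class:`TrainerContract`."""

    def __init__(self, channels: int = 3):
        self.channels = channels

    def fit(self, images, labels, design, weights, seed=0) -> TrainedModelHandle:
        X = np.asarray(images, dtype=np.float32)
        mu, sd = _standardize_fit(X)
        model = SmallResNet(channels=self.channels, n_classes=2, seed=seed)
        rec = sgdm_train(model, (X - mu) / sd, np.asarray(labels),
                         design.d_h, weights.weights, seed=seed)
        return TrainedModelHandle(model, design, {
            "task": "detection", "norm": (mu, sd),
            "n_steps": rec.n_steps, "n_epochs": rec.n_epochs,
            "grad_norms": rec.grad_norms, "final_loss": rec.losses[-1] if rec.losses else None,
        })

    def predict_probabilities(self, handle, images) -> np.ndarray:
        mu, sd = handle.metadata["norm"]
        X = (np.asarray(images, dtype=np.float32) - mu) / sd
        return predict_in_batches(handle.model, X)


class ReferenceSegmenter:
    """Small 3-level U-Net satisfying :class:`TrainerContract`."""

    def __init__(self, base_channels: int = 3):
        self.base_channels = base_channels

    def fit(self, images, labels, design, weights, seed=0) -> TrainedModelHandle:
        X = np.asarray(images, dtype=np.float32)
        mu, sd = _standardize_fit(X)
        model = SmallUNet(base_channels=self.base_channels, n_classes=N_CLASSES, seed=seed)
        rec = sgdm_train(model, (X - mu) / sd, np.asarray(labels),
                         design.d_h, weights.weights, seed=seed)
        return TrainedModelHandle(model, design, {
            "task": "segmentation", "norm": (mu, sd),
            "n_steps": rec.n_steps, "n_epochs": rec.n_epochs,
            "grad_norms": rec.grad_norms, "final_loss": rec.losses[-1] if rec.losses else None,
        })

    def predict_probabilities(self, handle, images) -> np.ndarray:
        mu, sd = handle.metadata["norm"]
        X = (np.asarray(images, dtype=np.float32) - mu) / sd
        return predict_in_batches(handle.model, X, batch=16)


def predict_l3_slice(backend, handle: TrainedModelHandle, volume: PatientVolume,
                     cfg: PreprocessConfig | None = None) -> int:
    """Index of the slice with the highest P(L3); ties -> lowest index."""
    if volume.n_slices == 0:
        raise ValueError("empty volume")
    cfg = cfg or PreprocessConfig()
    X = preprocess_volume(volume, cfg.detection_size, cfg)[:, None, :, :]
    probs = backend.predict_probabilities(handle, X)
    return int(np.argmax(probs[:, 1]))  # np.argmax returns the first maximum


def nearest_l3_error(predicted_index: int, volume: PatientVolume) -> int:
    """Signed slice error to the nearest L3-flagged slice (0 if predicted
    slice is itself L3); sign is predicted - true."""
    l3 = volume.l3_indices()
    nearest = l3[np.argmin(np.abs(l3 - predicted_index))]
    return int(predicted_index - nearest)
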