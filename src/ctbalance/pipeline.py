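"""End-to-end experiment orchestration.

One :func:`run_experiment` call reproduces the whole strategy on a phantom
cohort: generate (or load) patients, split patient-level folds, run
Bayesian optimization of the design vector on the training folds of each
requested fold round — once with the correction design variables (CDVs)
free, once with them pinned — train final models with the incumbent
designs, post-process segmentation predictions with the HU-range veto,
and evaluate slice errors, Bland–Altman agreement, overlap metrics and
tissue areas on the held-out test fold.

Design selection never sees the test fold: the BO objective is evaluated
on a fixed inner train/validation split of the training patients.

All randomness derives from ``config.seed``; re-running a config
reproduces every CSV byte-for-byte with the reference backend.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as M
from .bayesopt import DesignSpace, OptimizationResult, objective_from_counts, optimize
from .imbalance import (
    DesignVector,
    Hyperparameters,
    class_weight_minima,
    compute_class_weights,
    make_augmentation_plan,
)
from .phantom import PhantomParams, generate_cohort
from .postprocess import HURangeTable, hu_refine
from .preprocess import resize_mask
from .training import (
    PreprocessConfig,
    ReferenceDetector,
    ReferenceSegmenter,
    build_detection_dataset,
    build_segmentation_dataset,
    check_no_leakage,
    detection_class_counts,
    nearest_l3_error,
    predict_l3_slice,
    preprocess_volume,
    segmentation_pixel_frequencies,
    split_folds,
    _volumes,
)
from .types import N_CLASSES

logger = logging.getLogger(__name__)

ARM_WITH, ARM_WITHOUT = "with_cdv", "without_cdv"
FOREGROUND_CLASSES = (1, 2, 3, 4)  # SM, SAT, VAT, other


def subseed(master: int, *tags) -> int:
    """Deterministic sub-seed (< 2^31) from the master seed and a tag path."""
    h = hashlib.blake2b(f"{master}:{':'.join(map(str, tags))}".encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") & 0x7FFFFFFF


@dataclass
class RunConfig:
    tasks: tuple = ("detection", "segmentation")
    arms: tuple = (ARM_WITH, ARM_WITHOUT)
    n_patients: int = 40
    phantom: PhantomParams = field(default_factory=PhantomParams)
    k_folds: int = 5
    folds: tuple | None = (0,)  # fold rounds to run; None = all k
    bo_budget: int = 20
    n_init: int | None = None
    seed: int = 0
    aug_factor: int = 4
    weight_span: float = 10.0
    min_rule: str = "pixel_ratio"
    inner_val_fraction: float = 0.2
    baseline: str = "pinned"  # 'pinned' (BO over d_h) or 'none' (fixed mid-range d_h)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    out_dir: str | None = None

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        if "phantom" in d and isinstance(d["phantom"], dict):
            ph = d["phantom"]
            ph["tissue_hu_means"] = {int(k): v for k, v in ph.get("tissue_hu_means", {}).items()} or None
            ph["tissue_hu_sd"] = {int(k): v for k, v in ph.get("tissue_hu_sd", {}).items()} or None
            ph = {k: v for k, v in ph.items() if v is not None}
            d["phantom"] = PhantomParams(**ph)
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            pp = d["preprocess"]
            pp["window"] = tuple(pp["window"])
            pp["percentiles"] = tuple(pp["percentiles"])
            d["preprocess"] = PreprocessConfig(**pp)
        for key in ("tasks", "arms"):
            d[key] = tuple(d[key])
        if d.get("folds") is not None:
            d["folds"] = tuple(d["folds"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Objective builders (inner train/validation split; test fold never seen)
# ---------------------------------------------------------------------------

def _inner_split(train_pids: list, fraction: float, seed: int) -> tuple:
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(train_pids))
    n_val = max(1, int(round(fraction * len(train_pids))))
    val = [train_pids[i] for i in order[:n_val]]
    tr = [train_pids[i] for i in order[n_val:]]
    return sorted(tr), sorted(val)


def _detection_design(values: dict, minima: np.ndarray, pinned_ratio: float,
                      with_cdv: bool, min_rule: str):
    hp = Hyperparameters(**{k: values[k] for k in (
        "l2_regularization", "learning_rate", "batch_size",
        "gradient_threshold", "epochs", "momentum")})
    if with_cdv:
        d_a = values["d_a"]
        d_c = np.array([values[f"d_c_{k}"] for k in range(len(minima))])
    else:
        d_a = pinned_ratio
        d_c = minima.copy()
    return DesignVector(hp, d_a=d_a, d_c=d_c)


def _segmentation_design(values: dict, minima: np.ndarray, with_cdv: bool):
    hp = Hyperparameters(**{k: values[k] for k in (
        "l2_regularization", "learning_rate", "batch_size",
        "gradient_threshold", "epochs", "momentum")})
    if with_cdv:
        d_c = np.array([values[f"d_c_{k}"] for k in range(len(minima))])
    else:
        d_c = minima.copy()
    return DesignVector(hp, d_a=None, d_c=d_c)


class DetectionTask:
    """Builds objective, final trainer and test evaluation for detection."""

    name = "detection"

    def __init__(self, cohort, config: RunConfig, backend=None):
        self.cohort = cohort
        self.cfg = config
        self.backend = backend or ReferenceDetector()

    def _frequencies(self, pids) -> tuple:
        n_l3, n_non = detection_class_counts(self.cohort, pids)
        tot = n_l3 + n_non
        # class order: 0 = non-L3 (majority), 1 = L3 (minority)
        return np.array([n_non / tot, n_l3 / tot]), n_l3, n_non

    def space(self, inner_train, with_cdv: bool) -> tuple:
        freqs, n_l3, n_non = self._frequencies(inner_train)
        minima = class_weight_minima(freqs, "detection")
        if with_cdv:
            space = DesignSpace.detection(n_l3, n_non, minima, with_cdv=True,
                                          weight_span=self.cfg.weight_span)
        else:
            space = DesignSpace.hyperparameters()
        return space, minima, n_l3 / n_non

    def _train(self, pids, design: DesignVector, seed: int):
        freqs, n_l3, n_non = self._frequencies(pids)
        plan = make_augmentation_plan(n_l3, n_non, design.d_a, seed=subseed(seed, "plan"))
        X, y = build_detection_dataset(self.cohort, pids, plan, self.cfg.preprocess)
        weights = compute_class_weights(freqs, design.d_c, "detection")
        return self.backend.fit(X, y, design, weights, seed=seed)

    def objective_fn(self, inner_train, inner_val, minima, pinned_ratio,
                     with_cdv: bool, train_seed: int):
        val_vols = _volumes(self.cohort, inner_val)
        Xv = np.concatenate([
            preprocess_volume(v, self.cfg.preprocess.detection_size, self.cfg.preprocess)
            for v in val_vols
        ])[:, None, :, :]
        yv = np.concatenate([v.l3_flags.astype(np.intp) for v in val_vols])

        def fn(values: dict) -> float:
            design = _detection_design(values, minima, pinned_ratio, with_cdv,
                                       self.cfg.min_rule)
            handle = self._train(inner_train, design, train_seed)
            probs = self.backend.predict_probabilities(handle, Xv)
            pred = probs.argmax(axis=1)
            counts = M.confusion(pred, yv, n_classes=2)
            return objective_from_counts(counts, foreground_classes=[1])

        return fn

    def evaluate(self, design: DesignVector, train_pids, test_pids, seed: int) -> dict:
        handle = self._train(train_pids, design, seed)
        rows = []
        for v in _volumes(self.cohort, test_pids):
            pred = predict_l3_slice(self.backend, handle, v, self.cfg.preprocess)
            err = nearest_l3_error(pred, v)
            rows.append(dict(patient_id=v.patient_id, pred_index=pred,
                             true_index=pred - err, error=err))
        df = pd.DataFrame(rows)
        ba = M.bland_altman(df[["pred_index", "true_index"]].to_numpy())
        return {
            "predictions": df,
            "mean_abs_slice_error": float(df.error.abs().mean()),
            "sd_abs_slice_error": float(df.error.abs().std(ddof=1)) if len(df) > 1 else 0.0,
            "mean_signed_slice_error": float(df.error.mean()),
            "bland_altman": dataclasses.asdict(ba),
        }


class SegmentationTask:
    """Objective, final trainer and test evaluation for tissue segmentation."""

    name = "segmentation"

    def __init__(self, cohort, config: RunConfig, backend=None):
        self.cohort = cohort
        self.cfg = config
        self.backend = backend or ReferenceSegmenter()

    def minima_from(self, pids) -> np.ndarray:
        masks = []
        size = self.cfg.preprocess.segmentation_size
        for v in _volumes(self.cohort, pids):
            for i in v.l3_indices():
                masks.append(resize_mask(v.masks[i], size).codes)
        freqs = segmentation_pixel_frequencies(np.stack(masks))
        return class_weight_minima(freqs, "segmentation", self.cfg.min_rule), freqs

    def space(self, inner_train, with_cdv: bool) -> tuple:
        minima, freqs = self.minima_from(inner_train)
        if with_cdv:
            space = DesignSpace.segmentation(minima, with_cdv=True,
                                             weight_span=self.cfg.weight_span)
        else:
            space = DesignSpace.hyperparameters()
        return space, minima, freqs

    def _train(self, pids, design: DesignVector, freqs, seed: int):
        X, Mk = build_segmentation_dataset(self.cohort, pids, factor=self.cfg.aug_factor,
                                           seed=subseed(seed, "aug"), cfg=self.cfg.preprocess)
        weights = compute_class_weights(freqs, design.d_c, "segmentation",
                                        min_rule=self.cfg.min_rule)
        return self.backend.fit(X, Mk, design, weights, seed=seed)

    def _predict_codes(self, handle, v, i) -> np.ndarray:
        size = self.cfg.preprocess.segmentation_size
        from .preprocess import preprocess_slice

        img = preprocess_slice(v.slices[i], v.pixel_spacing_mm, size,
                               self.cfg.preprocess.window,
                               self.cfg.preprocess.percentiles).intensity
        probs = self.backend.predict_probabilities(
            handle, img[None, None, :, :].astype(np.float32))
        pred = probs[0].argmax(axis=0)
        return hu_refine(pred, np.asarray(v.slices[i], dtype=float), HURangeTable())

    def objective_fn(self, inner_train, inner_val, minima, freqs, with_cdv: bool,
                     train_seed: int):
        def fn(values: dict) -> float:
            design = _segmentation_design(values, minima, with_cdv)
            handle = self._train(inner_train, design, freqs, train_seed)
            preds, trues = [], []
            size = self.cfg.preprocess.segmentation_size
            for v in _volumes(self.cohort, inner_val):
                for i in v.l3_indices():
                    preds.append(self._predict_codes(handle, v, i))
                    trues.append(resize_mask(v.masks[i], size).codes)
            counts = M.confusion(np.stack(preds), np.stack(trues), n_classes=N_CLASSES)
            return objective_from_counts(counts, foreground_classes=FOREGROUND_CLASSES)

        return fn

    def evaluate(self, design: DesignVector, train_pids, test_pids, freqs, seed: int) -> dict:
        handle = self._train(train_pids, design, freqs, seed)
        size = self.cfg.preprocess.segmentation_size
        rows, areas = [], []
        for v in _volumes(self.cohort, test_pids):
            spacing_current = v.pixel_spacing_mm * (v.masks[0].native_size / size)
            for i in v.l3_indices():
                pred = self._predict_codes(handle, v, i)
                true = resize_mask(v.masks[i], size).codes
                sm = M.segmentation_metrics(pred, true, spacing_current,
                                            classes=FOREGROUND_CLASSES)
                for row in sm.as_rows():
                    rows.append(dict(patient_id=v.patient_id, slice_index=int(i), **row))
                native = v.masks[i].native_size
                for cls in FOREGROUND_CLASSES:
                    areas.append(dict(
                        patient_id=v.patient_id, slice_index=int(i), cls=cls,
                        pred_mm2=M.tissue_area(pred, cls, v.pixel_spacing_mm, native, size),
                        ref_mm2=M.tissue_area(true, cls, v.pixel_spacing_mm, native, size),
                    ))
        mdf = pd.DataFrame(rows)
        adf = pd.DataFrame(areas)
        r2 = {}
        for cls in FOREGROUND_CLASSES:
            sub = adf[adf.cls == cls]
            try:
                r2[cls] = M.r_squared(sub.pred_mm2, sub.ref_mm2)
            except ValueError:
                r2[cls] = float("nan")
        return {
            "metrics": mdf,
            "areas": adf,
            "macro_dice": float(mdf.dice.mean()),
            "macro_jaccard": float(mdf.jaccard.mean()),
            "area_r2": r2,
        }


# ---------------------------------------------------------------------------
# The experiment loop
# ---------------------------------------------------------------------------

def _history_frame(result: OptimizationResult) -> pd.DataFrame:
    rows = []
    inc = np.inf
    for o in result.history:
        inc = min(inc, o.objective)
        rows.append(dict(iteration=o.index, objective=o.objective,
                         incumbent=inc, error=o.error or "", **o.values))
    return pd.DataFrame(rows)


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


def run_experiment(config: RunConfig, cohort: list | None = None) -> dict:
    """Run the full with-vs-without-CDV comparison; returns the summary dict
    (and writes all artifacts under ``config.out_dir`` when set)."""
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(config.to_yaml())
    logf = (out / "runlog.jsonl").open("w") if out else None

    if cohort is None:
        cohort = generate_cohort(config.phantom, config.n_patients,
                                 seed=subseed(config.seed, "cohort"))
    assignment = split_folds(cohort, k=config.k_folds, seed=subseed(config.seed, "folds"))
    check_no_leakage(assignment)
    if out:
        _write(pd.DataFrame(sorted(assignment.mapping.items()),
                            columns=["patient_id", "fold"]), out / "folds.csv")

    folds = tuple(range(config.k_folds)) if config.folds is None else tuple(config.folds)
    summary = {"config_seed": config.seed, "folds": list(folds), "results": []}

    for fold in folds:
        train_pids = assignment.train_patients(fold)
        test_pids = assignment.patients_in_fold(fold)
        inner_train, inner_val = _inner_split(
            train_pids, config.inner_val_fraction, subseed(config.seed, "inner", fold))
        for task_name in config.tasks:
            task = (DetectionTask if task_name == "detection" else SegmentationTask)(
                cohort, config)
            for arm in config.arms:
                with_cdv = arm == ARM_WITH
                tag = (fold, task_name, arm)
                train_seed = subseed(config.seed, "train", *tag)
                if task_name == "detection":
                    space, minima, pinned_ratio = task.space(inner_train, with_cdv)
                    obj = task.objective_fn(inner_train, inner_val, minima,
                                            pinned_ratio, with_cdv, train_seed)
                    to_design = lambda v: _detection_design(  # noqa: E731
                        v, minima, pinned_ratio, with_cdv, config.min_rule)
                else:
                    space, minima, freqs = task.space(inner_train, with_cdv)
                    obj = task.objective_fn(inner_train, inner_val, minima, freqs,
                                            with_cdv, train_seed)
                    to_design = lambda v: _segmentation_design(v, minima, with_cdv)  # noqa: E731

                if not with_cdv and config.baseline == "none":
                    best_values = {k: getattr(Hyperparameters.midrange(), k)
                                   for k in Hyperparameters.midrange().__dict__}
                    result = None
                else:
                    n_init = config.n_init
                    if n_init is None:
                        n_init = min(max(5, 2 * space.dim), max(2, config.bo_budget // 2))
                    result = optimize(obj, space, budget=config.bo_budget,
                                      n_init=n_init, seed=subseed(config.seed, "bo", *tag))
                    best_values = result.best_values
                    if logf:
                        for o in result.history:
                            logf.write(json.dumps({
                                "fold": fold, "task": task_name, "arm": arm,
                                "iteration": o.index, "objective": o.objective,
                                "values": o.values}, sort_keys=True) + "\n")

                design = to_design(best_values)
                # Final-model minima/frequencies come from the full training folds.
                if task_name == "detection":
                    ev = task.evaluate(design, train_pids, test_pids,
                                       seed=subseed(config.seed, "final", *tag))
                    record = dict(fold=fold, task=task_name, arm=arm,
                                  best_objective=None if result is None else result.best_objective,
                                  design=design.to_dict(),
                                  mean_abs_slice_error=ev["mean_abs_slice_error"],
                                  sd_abs_slice_error=ev["sd_abs_slice_error"],
                                  mean_signed_slice_error=ev["mean_signed_slice_error"],
                                  bland_altman=ev["bland_altman"])
                    if out:
                        _write(ev["predictions"],
                               out / f"fold{fold}" / f"detection_{arm}_predictions.csv")
                else:
                    full_minima, full_freqs = task.minima_from(train_pids)
                    if not with_cdv:
                        design = DesignVector(design.d_h, None, full_minima.copy())
                    ev = task.evaluate(design, train_pids, test_pids, full_freqs,
                                       seed=subseed(config.seed, "final", *tag))
                    record = dict(fold=fold, task=task_name, arm=arm,
                                  best_objective=None if result is None else result.best_objective,
                                  design=design.to_dict(),
                                  macro_dice=ev["macro_dice"],
                                  macro_jaccard=ev["macro_jaccard"],
                                  area_r2={str(k): v for k, v in ev["area_r2"].items()})
                    if out:
                        _write(ev["metrics"],
                               out / f"fold{fold}" / f"segmentation_{arm}_metrics.csv")
                        _write(ev["areas"],
                               out / f"fold{fold}" / f"segmentation_{arm}_areas.csv")
                summary["results"].append(record)
                if out:
                    if result is not None:
                        _write(_history_frame(result),
                               out / f"fold{fold}" / f"bo_history_{task_name}_{arm}.csv")
                    (out / f"fold{fold}" / f"design_{task_name}_{arm}.json").write_text(
                        design.to_json())
                logger.info("fold %d %s %s done", fold, task_name, arm)

    summary["comparison"] = _arm_comparison(summary["results"])
    if out:
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        _write(_summary_frame(summary["results"]), out / "summary.csv")
    if logf:
        logf.close()
    return summary


def _arm_comparison(results: list) -> dict:
    comp = {}
    for task, key in (("detection", "mean_abs_slice_error"), ("segmentation", "macro_dice")):
        vals = {}
        for arm in (ARM_WITH, ARM_WITHOUT):
            sel = [r[key] for r in results if r["task"] == task and r["arm"] == arm]
            if sel:
                vals[arm] = float(np.mean(sel))
        if vals:
            comp[task] = {key: vals}
    return comp


def _summary_frame(results: list) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {k: v for k, v in r.items() if not isinstance(v, dict)}
        if r["task"] == "detection":
            row["ba_fraction_within"] = r["bland_altman"]["fraction_within"]
        rows.append(row)
    return pd.DataFrame(rows)
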