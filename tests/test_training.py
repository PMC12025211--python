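"""Fold protocol, dataset builders, reference trainers and the L3 argmax rule."""

import numpy as np
import pytest

from ctbalance.imbalance import (
    DesignVector,
    Hyperparameters,
    class_weight_minima,
    compute_class_weights,
    make_augmentation_plan,
)
from ctbalance.nn import SmallResNet, SmallUNet, sgdm_train
from ctbalance.nn.layers import weighted_softmax_ce
from ctbalance.training import (
    PreprocessConfig,
    ReferenceDetector,
    ReferenceSegmenter,
    TrainedModelHandle,
    build_detection_dataset,
    build_segmentation_dataset,
    check_no_leakage,
    detection_class_counts,
    nearest_l3_error,
    predict_l3_slice,
    split_folds,
)


class TestFolds:
    def test_balanced_partition_and_coverage(self, tiny_cohort):
        fa = split_folds(tiny_cohort, k=4, seed=0)
        assert sorted(fa.fold_sizes()) == [2, 2, 2, 2]
        check_no_leakage(fa)
        union = set()
        for i in range(4):
            fold = set(fa.patients_in_fold(i))
            assert not (union & fold)
            union |= fold
        assert union == {v.patient_id for v in tiny_cohort}

    def test_uneven_sizes_differ_by_at_most_one(self, tiny_cohort):
        fa = split_folds(tiny_cohort[:7], k=5, seed=1)
        assert sorted(fa.fold_sizes()) == [1, 1, 1, 2, 2]

    def test_deterministic_given_seed(self, tiny_cohort):
        a = split_folds(tiny_cohort, k=4, seed=3)
        b = split_folds(tiny_cohort, k=4, seed=3)
        c = split_folds(tiny_cohort, k=4, seed=4)
        assert a.mapping == b.mapping
        assert a.mapping != c.mapping

    def test_too_few_patients_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            split_folds(tiny_cohort[:3], k=5, seed=0)


class TestDetectionDataset:
    def test_counts_hit_plan_target_exactly(self, tiny_cohort):
        train = [v.patient_id for v in tiny_cohort[:6]]
        n_l3, n_non = detection_class_counts(tiny_cohort, train)
        plan = make_augmentation_plan(n_l3, n_non, 0.5, seed=0)
        X, y = build_detection_dataset(tiny_cohort, train, plan)
        assert int(y.sum()) == plan.target_minority
        assert int((y == 0).sum()) == n_non
        assert X.shape[1:] == (1, 16, 16)

    def test_zero_augmentation_plan_gives_originals(self, tiny_cohort):
        train = [v.patient_id for v in tiny_cohort[:6]]
        n_l3, n_non = detection_class_counts(tiny_cohort, train)
        plan = make_augmentation_plan(n_l3, n_non, n_l3 / n_non, seed=0)
        X, y = build_detection_dataset(tiny_cohort, train, plan)
        assert len(y) == n_l3 + n_non

    def test_mismatched_plan_rejected(self, tiny_cohort):
        train = [v.patient_id for v in tiny_cohort[:6]]
        plan = make_augmentation_plan(3, 50, 0.5, seed=0)  # wrong counts
        with pytest.raises(ValueError, match="plan built for"):
            build_detection_dataset(tiny_cohort, train, plan)


class TestSegmentationDataset:
    def test_l3_only_and_factor(self, tiny_cohort):
        train = [v.patient_id for v in tiny_cohort[:6]]
        n_l3, _ = detection_class_counts(tiny_cohort, train)
        X, M = build_segmentation_dataset(tiny_cohort, train, factor=4, seed=0)
        assert len(X) == 4 * n_l3
        assert set(np.unique(M)) <= {0, 1, 2, 3, 4}

    def test_factor_one_originals_only(self, tiny_cohort):
        train = [v.patient_id for v in tiny_cohort[:3]]
        n_l3, _ = detection_class_counts(tiny_cohort, train)
        X, M = build_segmentation_dataset(tiny_cohort, train, factor=1, seed=0)
        assert len(X) == n_l3

    def test_image_and_mask_transformed_jointly(self, tiny_cohort):
        """Flipped copies keep image/mask alignment: the abdomen foreground
        footprint (bright pixels vs non-background codes) must still overlap."""
        train = [v.patient_id for v in tiny_cohort[:3]]
        X, M = build_segmentation_dataset(tiny_cohort, train, factor=3, seed=0)
        for img, mask in zip(X[:, 0], M):
            fg = mask > 0
            assert img[fg].mean() > img[~fg].mean()


class FixedProbBackend:
    """Stub backend returning pre-set L3 probabilities (argmax-rule tests)."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)

    def predict_probabilities(self, handle, images):
        p = self.probs[: len(images)]
        return np.stack([1 - p, p], axis=1)


class TestPredictL3:
    def _volume(self, tiny_cohort):
        return tiny_cohort[0]

    def test_argmax_and_tie_rule(self, tiny_cohort):
        v = tiny_cohort[0]
        probs = np.full(v.n_slices, 0.2)
        probs[7] = 0.9
        handle = TrainedModelHandle(None, None, {})
        assert predict_l3_slice(FixedProbBackend(probs), handle, v) == 7
        uniform = np.full(v.n_slices, 0.5)
        assert predict_l3_slice(FixedProbBackend(uniform), handle, v) == 0

    def test_nearest_l3_error_sign_and_zero_on_block(self, tiny_cohort):
        v = tiny_cohort[0]
        l3 = v.l3_indices()
        assert nearest_l3_error(int(l3[0]), v) == 0
        assert nearest_l3_error(int(l3[0]) - 2, v) == -2
        assert nearest_l3_error(int(l3[-1]) + 3, v) == 3


def _design(**kw):
    defaults = dict(learning_rate=5e-3, epochs=8, batch_size=10,
                    momentum=0.9, gradient_threshold=3, l2_regularization=1e-4)
    defaults.update(kw)
    return DesignVector(Hyperparameters(**defaults), d_a=0.5, d_c=np.array([1.0, 1.0]))


class TestReferenceTrainers:
    def _toy_separable(self, rng, n=80):
        """Bright-center vs dark-center 16x16 images: linearly separable."""
        X = rng.random((n, 1, 16, 16)).astype(np.float32) * 0.2
        y = rng.integers(0, 2, n)
        X[y == 1, :, 4:12, 4:12] += 0.7
        return np.clip(X, 0, 1), y

    def test_detector_reaches_perfect_f1_on_separable_toy(self, rng):
        X, y = self._toy_separable(rng)
        det = ReferenceDetector()
        f = np.array([max((y == 0).mean(), 1e-3), max((y == 1).mean(), 1e-3)])
        w = compute_class_weights(f / f.sum(), 1 / np.sqrt(f), "detection")
        handle = det.fit(X, y, _design(epochs=12), w, seed=0)
        pred = det.predict_probabilities(handle, X).argmax(axis=1)
        assert (pred == y).all()

    def test_gradient_clipping_contract(self, rng):
        X, y = self._toy_separable(rng, n=40)
        det = ReferenceDetector()
        w = compute_class_weights([0.5, 0.5], np.ones(2), "detection")
        handle = det.fit(X, y, _design(gradient_threshold=1, epochs=5), w, seed=0)
        norms = np.asarray(handle.metadata["grad_norms"])
        assert np.all(norms <= 1.0 + 1e-6)

    def test_epochs_change_step_count(self, rng):
        X, y = self._toy_separable(rng, n=40)
        det = ReferenceDetector()
        w = compute_class_weights([0.5, 0.5], np.ones(2), "detection")
        h5 = det.fit(X, y, _design(epochs=5), w, seed=0)
        h9 = det.fit(X, y, _design(epochs=9), w, seed=0)
        assert h9.metadata["n_steps"] == h5.metadata["n_steps"] * 9 // 5

    def test_same_seed_identical_predictions(self, rng):
        X, y = self._toy_separable(rng, n=40)
        det = ReferenceDetector()
        w = compute_class_weights([0.5, 0.5], np.ones(2), "detection")
        p1 = det.predict_probabilities(det.fit(X, y, _design(), w, seed=4), X)
        p2 = det.predict_probabilities(det.fit(X, y, _design(), w, seed=4), X)
        assert np.array_equal(p1, p2)

    def test_probability_rows_sum_to_one(self, rng):
        X, y = self._toy_separable(rng, n=16)
        det = ReferenceDetector()
        w = compute_class_weights([0.5, 0.5], np.ones(2), "detection")
        probs = det.predict_probabilities(det.fit(X, y, _design(epochs=5), w, seed=0), X)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_segmenter_probabilities_and_determinism(self, rng):
        X = rng.random((8, 1, 16, 16)).astype(np.float32)
        M = rng.integers(0, 5, (8, 16, 16))
        seg = ReferenceSegmenter()
        f = np.bincount(M.ravel(), minlength=5) / M.size
        w = compute_class_weights(f, f, "segmentation")
        d = DesignVector(Hyperparameters(epochs=5), d_c=f)
        probs = seg.predict_probabilities(seg.fit(X, M, d, w, seed=1), X)
        assert probs.shape == (8, 5, 16, 16)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        probs2 = seg.predict_probabilities(seg.fit(X, M, d, w, seed=1), X)
        assert np.array_equal(probs, probs2)


class TestBackpropCorrectness:
    """Analytic gradients agree with central finite differences."""

    @pytest.mark.parametrize("key", ["stem_W", "b1b_W", "fc_W"])
    def test_resnet_gradients(self, rng, key):
        m = SmallResNet(channels=3, seed=1, dtype=np.float64)
        x = rng.normal(size=(3, 1, 8, 8))
        y = np.array([0, 1, 1])
        w = np.array([1.0, 1.3])

        def loss():
            l, _ = weighted_softmax_ce(m.forward(x), y, w)
            return l

        _, d = weighted_softmax_ce(m.forward(x), y, w)
        m.backward(d)
        g = m.grads[key]
        idx = tuple(rng.integers(0, s) for s in g.shape)
        eps = 1e-6
        m.params[key][idx] += eps
        lp = loss()
        m.params[key][idx] -= 2 * eps
        lm = loss()
        m.params[key][idx] += eps
        assert g[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-7)

    @pytest.mark.parametrize("key", ["e1_W", "bo_W", "d1_W", "out_W"])
    def test_unet_gradients(self, rng, key):
        m = SmallUNet(base_channels=2, seed=1, dtype=np.float64)
        x = rng.normal(size=(2, 1, 8, 8))
        ym = rng.integers(0, 5, (2, 8, 8))
        w = np.ones(5)

        def loss():
            lg = m.forward(x)
            l, _ = weighted_softmax_ce(lg.transpose(0, 2, 3, 1).reshape(-1, 5),
                                       ym.reshape(-1), w)
            return l

        lg = m.forward(x)
        _, d = weighted_softmax_ce(lg.transpose(0, 2, 3, 1).reshape(-1, 5),
                                   ym.reshape(-1), w)
        m.backward(d.reshape(2, 8, 8, 5).transpose(0, 3, 1, 2))
        g = m.grads[key]
        idx = tuple(rng.integers(0, s) for s in g.shape)
        eps = 1e-6
        m.params[key][idx] += eps
        lp = loss()
        m.params[key][idx] -= 2 * eps
        lm = loss()
        m.params[key][idx] += eps
        assert g[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-7)
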