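"""Correction design variables: augmentation plans, transforms, class weights."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctbalance.imbalance import (
    DesignVector,
    Hyperparameters,
    augment_arrays,
    class_weight_minima,
    compute_class_weights,
    make_augmentation_plan,
    segmentation_augment,
    weighted_cross_entropy,
)


class TestAugmentationPlan:
    def test_clinical_regime_arithmetic(self):
        # 380 minority vs 10984 majority at ratio 0.20 (inside the optimal
        # 17-24% band): target = round(0.20 * 10984) = 2197
        plan = make_augmentation_plan(380, 10984, 0.20, seed=0)
        assert plan.target_minority == 2197
        assert plan.n_augmented_needed == 1817

    def test_full_balance_upper_bound(self):
        plan = make_augmentation_plan(380, 10984, 1.0, seed=0)
        assert plan.target_minority == 10984  # exact 1:1

    def test_no_augmentation_when_target_below_minority(self):
        plan = make_augmentation_plan(380, 10984, 0.02, seed=0)
        assert plan.n_augmented_needed == 0
        assert plan.op_sequence == []

    def test_ratio_bounds_enforced(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                make_augmentation_plan(10, 100, bad, seed=0)

    def test_plan_deterministic_and_cycles_sources(self):
        a = make_augmentation_plan(5, 100, 0.2, seed=3)
        b = make_augmentation_plan(5, 100, 0.2, seed=3)
        assert a.op_sequence == b.op_sequence
        assert [op[0] for op in a.op_sequence] == [i % 5 for i in range(a.n_augmented_needed)]


class TestTransforms:
    def test_flips_are_involutions(self, rng):
        img = rng.random((12, 12))
        for tf in ("hflip", "vflip"):
            once, _ = augment_arrays(img, None, tf, 0)
            twice, _ = augment_arrays(once, None, tf, 0)
            assert np.array_equal(twice, img)

    def test_vflip_reverses_rows(self):
        img = np.array([[0.1, 0.2], [0.3, 0.4]])
        out, _ = augment_arrays(img, None, "vflip", 0)
        assert np.array_equal(out, img[::-1])

    def test_rotation_preserves_mask_labels_and_range(self, rng):
        img = rng.random((16, 16))
        mask = rng.integers(0, 5, (16, 16)).astype(np.uint8)
        out, m = augment_arrays(img, mask, "rotation", 42)
        assert out.shape == img.shape
        assert out.min() >= 0.0 and out.max() <= 1.0
        assert set(np.unique(m)) <= set(np.unique(mask)) | {0}

    def test_rotation_seed_determinism(self, rng):
        img = rng.random((16, 16))
        a, _ = augment_arrays(img, None, "rotation", 7)
        b, _ = augment_arrays(img, None, "rotation", 7)
        c, _ = augment_arrays(img, None, "rotation", 8)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_unknown_transform_rejected(self):
        with pytest.raises(ValueError):
            augment_arrays(np.zeros((4, 4)), None, "shear", 0)


class TestSegmentationAugment:
    def test_factor_four_counts_and_originals_retained(self, rng):
        imgs = [rng.random((8, 8)) for _ in range(5)]
        masks = [rng.integers(0, 5, (8, 8)) for _ in range(5)]
        out_i, out_m = segmentation_augment(imgs, masks, factor=4, seed=0)
        assert len(out_i) == 20 and len(out_m) == 20
        for a, b in zip(out_i[:5], imgs):
            assert np.array_equal(a, b)

    def test_factor_one_is_identity(self, rng):
        imgs = [rng.random((8, 8))]
        masks = [rng.integers(0, 5, (8, 8))]
        out_i, out_m = segmentation_augment(imgs, masks, factor=1, seed=0)
        assert len(out_i) == 1 and np.array_equal(out_i[0], imgs[0])

    def test_seed_reproducibility(self, rng):
        imgs = [rng.random((8, 8)) for _ in range(3)]
        masks = [rng.integers(0, 5, (8, 8)) for _ in range(3)]
        a, _ = segmentation_augment(imgs, masks, factor=3, seed=5)
        b, _ = segmentation_augment(imgs, masks, factor=3, seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestClassWeights:
    def test_detection_minima_inverse_sqrt(self):
        f = np.array([0.9666, 0.0334])
        minima = class_weight_minima(f, "detection")
        assert minima[1] == pytest.approx(5.4718, abs=1e-3)
        assert minima[0] == pytest.approx(1.0171, abs=1e-3)

    def test_segmentation_minima_rules(self):
        f = np.array([0.5, 0.3, 0.2])
        assert np.allclose(class_weight_minima(f, "segmentation"), f)
        assert np.allclose(
            class_weight_minima(f, "segmentation", "inverse_pixel_ratio"), 1 / f)

    def test_zero_frequency_names_class(self):
        with pytest.raises(ValueError, match="class 1"):
            class_weight_minima(np.array([1.0, 0.0]), "detection")

    def test_weights_clamped_and_normalized(self):
        f = np.array([0.5, 0.5])
        cw = compute_class_weights(f, class_weight_minima(f, "detection"), "detection")
        assert np.allclose(cw.weights, [1.0, 1.0])  # symmetric case
        cw2 = compute_class_weights(f, np.array([1.0, 3.0]), "detection")
        assert cw2.weights.mean() == pytest.approx(1.0)
        # ordering preserved: class 1 got the larger multiplier
        assert cw2.weights[1] > cw2.weights[0]

    @given(st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None)
    def test_constraint_holds_up_to_rescale(self, seed):
        r = np.random.default_rng(seed)
        f = r.dirichlet(np.ones(4)) * 0.98 + 0.005
        f = f / f.sum()
        d_c = r.uniform(0.1, 5.0, size=4)
        cw = compute_class_weights(f, d_c, "detection")
        raw = np.maximum(cw.minima, d_c)
        assert np.allclose(cw.weights, raw / raw.mean())


    def test_weight_vector_json_roundtrip(self):
        from ctbalance.imbalance import ClassWeightVector

        f = np.array([0.7, 0.3])
        cw = compute_class_weights(f, np.array([1.0, 2.0]), "detection")
        back = ClassWeightVector.from_json(cw.to_json())
        assert np.allclose(back.weights, cw.weights)
        assert np.allclose(back.minima, cw.minima)
        assert back.task == "detection"


class TestWeightedCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        p = np.eye(3)[[0, 1, 2]]
        assert weighted_cross_entropy(p, [0, 1, 2], np.ones(3)) == pytest.approx(0.0, abs=1e-9)

    def test_half_probability_gives_ln2(self):
        p = np.array([[0.5, 0.5], [0.5, 0.5]])
        assert weighted_cross_entropy(p, [0, 1], np.ones(2)) == pytest.approx(np.log(2))

    def test_linear_in_weights_and_matches_unweighted(self, rng):
        p = rng.dirichlet(np.ones(4), size=10)
        y = rng.integers(0, 4, 10)
        base = weighted_cross_entropy(p, y, np.ones(4))
        doubled = weighted_cross_entropy(p, y, 2 * np.ones(4))
        assert doubled == pytest.approx(2 * base)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_cross_entropy(np.ones((2, 2)) / 2, [0], np.ones(2))


class TestDesignVector:
    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            Hyperparameters(learning_rate=1.0).validate()
        with pytest.raises(ValueError):
            DesignVector(Hyperparameters(), d_a=1.5)

    def test_json_roundtrip(self):
        d = DesignVector(Hyperparameters(), d_a=0.4, d_c=np.array([1.0, 2.0]))
        back = DesignVector.from_dict(d.to_dict())
        assert back.d_a == d.d_a
        assert np.allclose(back.d_c, d.d_c)
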