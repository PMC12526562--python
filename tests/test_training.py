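"""Dice loss, augmentation, dataset expansion, splits and the train loop."""

import numpy as np
import pandas as pd
import pytest

from scaseg import (
    AugmentConfig, LabelVolume, TrainConfig, VolumeGrid, augment_volume,
    build_network, expand_training_set, one_hot, segment, soft_dice_loss,
    soft_dice_loss_grad, stratified_split, train,
)
from scaseg.training import _rigid_transform
from .conftest import smoke_model_config, smoke_pairs


class TestSoftDiceLoss:
    def test_perfect_prediction_near_zero(self, rng):
        target = np.zeros((4, 6, 6, 6), dtype=np.float32)
        codes = rng.integers(0, 4, (6, 6, 6))
        for c in range(4):
            target[c] = codes == c
        assert soft_dice_loss(target, target) < 1e-4

    def test_hand_computed_two_channel_example(self):
        # single voxel, target (1,0), prediction (0.5,0.5):
        # DSC = (2*0.5/(0.5+1), 0) = (2/3, 0) -> loss = 1 - 1/3 = 2/3
        pred = np.array([0.5, 0.5], dtype=np.float32).reshape(2, 1, 1, 1)
        target = np.array([1.0, 0.0], dtype=np.float32).reshape(2, 1, 1, 1)
        assert soft_dice_loss(pred, target, eps=1e-12) == pytest.approx(2 / 3, abs=1e-6)

    def test_invariant_under_common_permutation(self, rng):
        pred = rng.random((4, 64)).astype(np.float32)
        pred /= pred.sum(axis=0)
        target = np.zeros_like(pred)
        target[rng.integers(0, 4, 64), np.arange(64)] = 1
        perm = rng.permutation(64)
        a = soft_dice_loss(pred.reshape(4, 4, 4, 4), target.reshape(4, 4, 4, 4))
        b = soft_dice_loss(pred[:, perm].reshape(4, 4, 4, 4),
                           target[:, perm].reshape(4, 4, 4, 4))
        assert a == pytest.approx(b, abs=1e-7)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            pred = rng.random((4, 3, 3, 3)).astype(np.float32)
            pred /= pred.sum(axis=0)
            target = np.zeros_like(pred)
            codes = rng.integers(0, 4, (3, 3, 3))
            for c in range(4):
                target[c] = codes == c
            loss = soft_dice_loss(pred, target)
            assert 0.0 <= loss <= 1.0

    def test_gradient_matches_finite_differences(self, rng):
        pred = rng.random((2, 3, 3, 3)).astype(np.float64)
        target = (rng.random((2, 3, 3, 3)) > 0.5).astype(np.float64)
        loss, grad = soft_dice_loss_grad(pred, target, eps=1e-5)
        eps = 1e-7
        for idx in [(0, 0, 0, 0), (1, 2, 1, 2), (0, 1, 2, 0)]:
            p2 = pred.copy(); p2[idx] += eps
            p3 = pred.copy(); p3[idx] -= eps
            num = (soft_dice_loss(p2, target) - soft_dice_loss(p3, target)) / (2 * eps)
            assert grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            soft_dice_loss(np.zeros((4, 2, 2, 2)), np.zeros((4, 2, 2, 3)))


class TestAugmentation:
    def _pair(self, rng, shape=(16, 16, 16)):
        img = VolumeGrid(rng.normal(size=shape))
        lab = LabelVolume(rng.integers(0, 4, shape).astype(np.int16))
        return img, lab

    def test_zero_ranges_identity(self, rng):
        img, lab = self._pair(rng)
        cfg = AugmentConfig(rotation_range_deg=0, translation_range_vox=0,
                            flip_probability=0)
        img2, lab2 = augment_volume(img, lab, cfg, seed=0)
        np.testing.assert_array_equal(img2.data, img.data)
        np.testing.assert_array_equal(lab2.data, lab.data)

    def test_label_codes_subset_after_augmentation(self, rng):
        img, lab = self._pair(rng)
        cfg = AugmentConfig(seed=0)
        _, lab2 = augment_volume(img, lab, cfg, seed=7)
        assert set(np.unique(lab2.data)) <= set(np.unique(lab.data)) | {0}

    def test_double_flip_is_identity(self, rng):
        img, lab = self._pair(rng)
        i2, l2 = _rigid_transform(img, lab, (0, 0, 0), (0, 0, 0), flip=True)
        i3, l3 = _rigid_transform(i2, l2, (0, 0, 0), (0, 0, 0), flip=True)
        np.testing.assert_allclose(i3.data, img.data, atol=1e-10)
        np.testing.assert_array_equal(l3.data, lab.data)

    def test_same_seed_same_output(self, rng):
        img, lab = self._pair(rng)
        cfg = AugmentConfig()
        a = augment_volume(img, lab, cfg, seed=5)
        b = augment_volume(img, lab, cfg, seed=5)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[1].data, b[1].data)

    def test_integer_translation_moves_labels_exactly(self, rng):
        lab_data = np.zeros((16, 16, 16), dtype=np.int16)
        lab_data[6:10, 6:10, 6:10] = 2
        img = VolumeGrid(rng.normal(size=(16, 16, 16)))
        lab = LabelVolume(lab_data)
        _, lab2 = _rigid_transform(img, lab, (0, 0, 0), (2, -1, 3), flip=False)
        np.testing.assert_array_equal(lab2.data[8:12, 5:9, 9:13], 2)
        assert (lab2.data == 2).sum() == 64


class TestExpandTrainingSet:
    @pytest.mark.parametrize("n_pairs,copies,expected",
                             [(17, 40, 697), (3, 40, 123), (4, 0, 4)])
    def test_expansion_bookkeeping(self, rng, n_pairs, copies, expected):
        shape = (16, 16, 16)
        pairs = [(VolumeGrid(rng.normal(size=shape)),
                  LabelVolume(rng.integers(0, 4, shape).astype(np.int16)))
                 for _ in range(n_pairs)]
        out = expand_training_set(pairs, AugmentConfig(copies_per_image=copies, seed=0))
        assert len(out) == expected
        for orig, got in zip(pairs, out[:n_pairs]):
            np.testing.assert_array_equal(orig[0].data, got[0].data)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            expand_training_set([], AugmentConfig())


class TestStratifiedSplit:
    def _manifest(self):
        rows = [{"subject_id": f"p{i}", "group": "patient"} for i in range(13)]
        rows += [{"subject_id": f"q{i}", "group": "preclinical"} for i in range(7)]
        rows += [{"subject_id": f"c{i}", "group": "control"} for i in range(5)]
        return pd.DataFrame(rows)

    def test_17_3_5_partition_has_all_groups_everywhere(self):
        m = self._manifest()
        tr, va, te = stratified_split(m, (17, 3, 5), seed=0)
        assert (len(tr), len(va), len(te)) == (17, 3, 5)
        all_ids = sorted(pd.concat([tr, va, te])["subject_id"])
        assert all_ids == sorted(m["subject_id"])
        for part in (tr, va, te):
            assert set(part["group"]) == {"patient", "preclinical", "control"}

    def test_overfull_request_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(self._manifest(), (20, 10, 5), seed=0)

    def test_deterministic_under_seed(self):
        m = self._manifest()
        a = stratified_split(m, (17, 3, 5), seed=9)
        b = stratified_split(m, (17, 3, 5), seed=9)
        for x, y in zip(a, b):
            assert x.equals(y)


class TestTrainLoop:
    def test_zero_epochs_is_noop(self):
        pairs = smoke_pairs(2, seed=0)
        handle = build_network(smoke_model_config(), seed=0)
        before = [p.value.copy() for p in handle.net.params()]
        handle, hist = train(handle, pairs, None, TrainConfig(epochs=0))
        assert len(hist) == 0
        for p, b in zip(handle.net.params(), before):
            np.testing.assert_array_equal(p.value, b)

    def test_loss_decreases_and_history_is_reproducible(self):
        pairs = smoke_pairs(3, seed=1)
        cfg = TrainConfig(epochs=3, learning_rate=3e-3, seed=5)
        h1, hist1 = train(build_network(smoke_model_config(), seed=2),
                          pairs[:2], pairs[2:], cfg)
        h2, hist2 = train(build_network(smoke_model_config(), seed=2),
                          pairs[:2], pairs[2:], cfg)
        assert hist1.equals(hist2)
        assert len(hist1) == 3
        assert hist1["train_loss"].iloc[-1] < hist1["train_loss"].iloc[0]

    def test_segment_output_contract(self):
        pairs = smoke_pairs(1, seed=2)
        handle = build_network(smoke_model_config(), seed=0)
        pred = segment(handle, pairs[0][0])
        assert pred.shape == pairs[0][0].shape
        assert set(np.unique(pred.data)) <= {0, 1, 2, 3}
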