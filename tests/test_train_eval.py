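"""Schedule closed form, cross-entropy gradient, mIoU conventions, training
mechanics on tiny inputs."""
import math

import numpy as np
import pytest

import ilwdeeplab as I
from ilwdeeplab.train import TrainConfig, cross_entropy, train_arrays


class TestPolySchedule:
    def test_endpoints(self):
        assert I.poly_lr(0, 100, 0.05) == pytest.approx(0.05)
        assert I.poly_lr(100, 100, 0.05) == 0.0

    def test_halfway_closed_form(self):
        assert I.poly_lr(50, 100, 0.01, 0.9) == pytest.approx(
            0.01 * 0.5 ** 0.9, rel=1e-12)
        assert I.poly_lr(50, 100, 0.01, 0.9) == pytest.approx(0.0053589,
                                                              abs=5e-8)

    def test_monotone_nonincreasing_on_grid(self):
        vals = [I.poly_lr(t, 1000, 0.1) for t in range(0, 1001, 7)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_machine_precision_against_direct_formula(self):
        for t in range(0, 501, 13):
            expect = 0.05 * (1 - t / 500) ** 0.9
            assert I.poly_lr(t, 500, 0.05) == expect

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            I.poly_lr(0, 0, 0.1)
        with pytest.raises(ValueError):
            I.poly_lr(-1, 10, 0.1)
        with pytest.raises(ValueError):
            I.poly_lr(11, 10, 0.1)


class TestCrossEntropy:
    def test_matches_manual_softmax_loss(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(2, 3, 4, 4)).astype(np.float32)
        labels = rng.integers(0, 3, size=(2, 4, 4))
        loss, _ = cross_entropy(logits, labels)
        p = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        manual = -np.mean([math.log(p[n, labels[n, i, j], i, j])
                           for n in range(2) for i in range(4)
                           for j in range(4)])
        assert loss == pytest.approx(manual, rel=1e-5)

    def test_gradient_numerically(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(1, 3, 2, 2)).astype(np.float64)
        labels = rng.integers(0, 3, size=(1, 2, 2))
        _, grad = cross_entropy(logits.astype(np.float32), labels)
        eps = 1e-4
        for c in range(3):
            pert = logits.copy()
            pert[0, c, 0, 0] += eps
            lp, _ = cross_entropy(pert.astype(np.float32), labels)
            lm, _ = cross_entropy(logits.astype(np.float32), labels)
            assert grad[0, c, 0, 0] == pytest.approx((lp - lm) / eps,
                                                     abs=1e-2)


class TestMeanIoU:
    def test_perfect_prediction_scores_one(self):
        rng = np.random.default_rng(2)
        maps = rng.integers(0, 4, size=(3, 6, 6))
        assert I.mean_iou(maps, maps, 4).miou == 1.0

    def test_hand_enumerated_2x2_example(self):
        gt = np.array([[0, 0], [1, 1]])
        pred = np.array([[0, 1], [1, 1]])
        res = I.mean_iou(gt, pred, 2)
        assert res.per_image_class_iou[0, 0] == pytest.approx(0.5)
        assert res.per_image_class_iou[0, 1] == pytest.approx(2 / 3)
        assert res.miou == pytest.approx(7 / 12)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 3, size=(2, 5, 5))
        b = rng.integers(0, 3, size=(2, 5, 5))
        assert I.mean_iou(a, b, 3).miou == pytest.approx(
            I.mean_iou(b, a, 3).miou)

    def test_empty_union_conventions(self):
        gt = np.zeros((1, 3, 3), int)          # class 1 absent everywhere
        pred = np.zeros((1, 3, 3), int)
        assert I.mean_iou(gt, pred, 2, "skip").miou == 1.0
        assert I.mean_iou(gt, pred, 2, "one").miou == 1.0
        assert I.mean_iou(gt, pred, 2, "zero").miou == 0.5

    def test_matches_brute_force_set_computation(self):
        """Implementation vs an independent per-pixel set-based oracle."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            k = int(rng.integers(2, 5))
            gt = rng.integers(0, k, size=(4, 4))
            pred = rng.integers(0, k, size=(4, 4))
            ious = []
            for c in range(k):
                g = {(i, j) for i in range(4) for j in range(4)
                     if gt[i, j] == c}
                p = {(i, j) for i in range(4) for j in range(4)
                     if pred[i, j] == c}
                if g | p:
                    ious.append(len(g & p) / len(g | p))
            expect = sum(ious) / len(ious)
            assert I.mean_iou(gt, pred, k).miou == pytest.approx(expect)

    def test_zero_images_rejected(self):
        with pytest.raises(ValueError):
            I.mean_iou(np.zeros((0, 2, 2), int), np.zeros((0, 2, 2), int), 2)


class TestTrainingMechanics:
    def _toy_data(self, n=4, side=32, k=3):
        spec = I.SceneSpec(seed=0, num_classes=k, canvas_side=side)
        samples = [I.generate_scene(spec, i) for i in range(n)]
        X = np.stack([s.image for s in samples]).astype(np.float32) / 255.0
        return (np.ascontiguousarray(X.transpose(0, 3, 1, 2)),
                np.stack([s.labels for s in samples]))

    def test_one_epoch_small_set_is_one_step_at_base_lr(self):
        X, y = self._toy_data(n=4)
        model = I.ILWDeepLab(I.ilw_config(3, seed=0))
        cfg = TrainConfig(epochs=1, batch_size=8, base_lr=0.05, seed=0,
                          input_side=32)
        res = train_arrays(model, X, y, cfg)
        assert len(res.loss_trace) == 1
        assert res.lr_trace == [0.05]

    def test_zero_lr_leaves_weights_bit_identical(self):
        X, y = self._toy_data(n=2)
        model = I.ILWDeepLab(I.ilw_config(3, seed=0))
        before = {k: v.copy() for k, v in model.state_dict().items()}
        opt_cfg = TrainConfig(epochs=1, batch_size=2, base_lr=1e-30, seed=0,
                              input_side=32, weight_decay=0.0)
        # lr numerically zero after the first poly step would still move
        # weights; instead verify the optimizer's explicit zero-lr guard
        from ilwdeeplab.nn import SGD
        opt = SGD(model.parameters(), lr=0.0, momentum=0.9)
        logits = model.forward(X, training=True)
        loss, grad = cross_entropy(logits, y)
        model.zero_grad()
        model.backward(grad)
        opt.step()
        after = model.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_loss_decreases_on_tiny_set(self):
        """A few epochs on a 4-image 32x32 set reduce the mean loss."""
        X, y = self._toy_data(n=4)
        model = I.ILWDeepLab(I.ilw_config(3, seed=0))
        cfg = TrainConfig(epochs=6, batch_size=4, base_lr=0.05, seed=0,
                          input_side=32)
        res = train_arrays(model, X, y, cfg)
        assert res.final_loss < res.initial_loss

    def test_empty_manifest_rejected(self):
        model = I.ILWDeepLab(I.ilw_config(3, seed=0))
        with pytest.raises(ValueError):
            train_arrays(model, np.zeros((0, 3, 32, 32), np.float32),
                         np.zeros((0, 32, 32), int),
                         TrainConfig(epochs=1, input_side=32))

    def test_schedule_length(self):
        X, y = self._toy_data(n=4)
        model = I.ILWDeepLab(I.ilw_config(3, seed=0))
        cfg = TrainConfig(epochs=3, batch_size=2, base_lr=0.05, seed=0,
                          input_side=32)
        res = train_arrays(model, X, y, cfg)
        assert len(res.loss_trace) == 3 * 2
        assert res.lr_trace[0] == 0.05
        assert res.lr_trace[-1] == pytest.approx(
            I.poly_lr(5, 6, 0.05))
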