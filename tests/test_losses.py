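"""Loss functions against independent oracles and worked values."""

import numpy as np
import pytest

from meniscus3d.autodiff import Tensor
from meniscus3d.losses import (class_weights, giou_loss, l1_box_loss,
                               total_loss, voxelized_giou_oracle, weighted_bce)


def _corners_to_cs(lo, hi):
    """Corner-form box -> center+size 6-vector."""
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    return np.concatenate([(lo + hi) / 2.0, hi - lo])


class TestClassWeights:
    def test_balanced_class_gets_unit_weight(self):
        labels = np.zeros((100, 6), int)
        labels[:50] = 1
        assert np.allclose(class_weights(labels), 1.0)

    def test_quarter_prevalence_doubles_weight(self):
        labels = np.zeros((100, 6), int)
        labels[:25] = 1
        assert np.allclose(class_weights(labels), 2.0)

    def test_permutation_invariant(self, rng):
        labels = (rng.random((40, 6)) < 0.3).astype(int)
        labels[0] = 1
        labels[1] = 0
        perm = rng.permutation(40)
        assert np.allclose(class_weights(labels), class_weights(labels[perm]))

    def test_degenerate_class_rejected(self):
        labels = np.zeros((10, 6), int)
        with pytest.raises(ValueError):
            class_weights(labels)


class TestWeightedBCE:
    def test_chance_logit_gives_ln2(self):
        loss = weighted_bce(np.zeros((1, 6)), np.ones((1, 6)), np.ones(6))
        assert loss.item() == pytest.approx(6 * np.log(2), rel=1e-6)

    def test_confident_correct_predictions_vanish(self):
        targets = np.array([[1, 0, 1, 0, 1, 0]], dtype=float)
        logits = (2 * targets - 1) * 50.0
        assert weighted_bce(logits, targets, np.ones(6)).item() < 1e-6

    def test_matches_naive_double_loop_oracle(self, rng):
        logits = rng.normal(scale=2.0, size=(7, 6))
        targets = (rng.random((7, 6)) < 0.5).astype(float)
        w = rng.uniform(0.5, 3.0, 6)
        loss = weighted_bce(logits, targets, w).item()

        def sigmoid(z):
            return 1.0 / (1.0 + np.exp(-z))

        acc = 0.0
        for c in range(6):
            for i in range(7):
                y, z = targets[i, c], logits[i, c]
                acc += w[c] * (y * np.log(sigmoid(z))
                               + (1 - y) * np.log(1 - sigmoid(z)))
        assert loss == pytest.approx(-acc / 7, abs=1e-6)

    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.normal(size=(3, 6)).astype(np.float32)
        targets = (rng.random((3, 6)) < 0.5).astype(np.float64)
        w = np.ones(6)
        t = Tensor(logits, requires_grad=True)
        weighted_bce(t, targets, w).backward()

        def oracle(z):
            # float64 naive formulation, independent of the implementation
            s = 1.0 / (1.0 + np.exp(-z))
            per = targets * np.log(s) + (1 - targets) * np.log(1 - s)
            return -(w * per).sum() / z.shape[0]

        eps = 1e-5
        z64 = logits.astype(np.float64)
        for idx in [(0, 0), (1, 3), (2, 5)]:
            pert = z64.copy()
            pert[idx] += eps
            up = oracle(pert)
            pert[idx] -= 2 * eps
            num = (up - oracle(pert)) / (2 * eps)
            assert t.grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-6)

    def test_non_binary_targets_rejected(self):
        with pytest.raises(ValueError):
            weighted_bce(np.zeros((1, 6)), np.full((1, 6), 0.5), np.ones(6))


class TestL1BoxLoss:
    def test_perfect_prediction_is_zero(self, rng):
        b = rng.random((4, 12))
        assert l1_box_loss(b, b.copy()).item() == 0.0

    def test_uniform_offset_worked_value(self):
        p = np.zeros((1, 12))
        t = np.full((1, 12), 0.1)
        assert l1_box_loss(p, t).item() == pytest.approx(1.2, rel=1e-5)

    def test_homogeneous_in_the_differences(self, rng):
        p = rng.random((3, 12))
        t = rng.random((3, 12))
        base = l1_box_loss(p, t).item()
        scaled = l1_box_loss(t + 3.0 * (p - t), t).item()
        assert scaled == pytest.approx(3.0 * base, rel=1e-4)


class TestGIoU:
    def test_identical_boxes_give_zero_loss(self):
        box = _corners_to_cs([0.2, 0.3, 0.1], [0.6, 0.8, 0.5])
        assert giou_loss(box, box.copy()).item() == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_corner_cubes_worked_value(self):
        a = _corners_to_cs([0, 0, 0], [0.25, 0.25, 0.25])
        b = _corners_to_cs([0.75, 0.75, 0.75], [1, 1, 1])
        assert giou_loss(a, b).item() == pytest.approx(1.96875, rel=1e-5)

    def test_half_offset_cubes_worked_value(self):
        a = _corners_to_cs([0, 0, 0], [0.5, 0.5, 0.5])
        b = _corners_to_cs([0.25, 0.25, 0.25], [0.75, 0.75, 0.75])
        assert giou_loss(a, b).item() == pytest.approx(1.37778, rel=1e-4)

    def test_symmetric_and_translation_invariant(self, rng):
        for _ in range(20):
            c = rng.uniform(0.3, 0.7, (2, 3))
            s = rng.uniform(0.05, 0.3, (2, 3))
            a = np.concatenate([c[0], s[0]])
            b = np.concatenate([c[1], s[1]])
            assert giou_loss(a, b).item() == pytest.approx(
                giou_loss(b, a).item(), rel=1e-6)
            shift = rng.uniform(-0.2, 0.2, 3)
            a2 = a.copy()
            b2 = b.copy()
            a2[:3] += shift
            b2[:3] += shift
            if (a2[:3] >= 0).all() and (a2[:3] <= 1).all() \
                    and (b2[:3] >= 0).all() and (b2[:3] <= 1).all():
                assert giou_loss(a2, b2).item() == pytest.approx(
                    giou_loss(a, b).item(), abs=1e-5)

    def test_range_and_enclosure_reduction(self, rng):
        # loss in [0, 2); equals 1 - IoU when one box's envelope contains the other
        for _ in range(50):
            c = rng.uniform(0.35, 0.65, (2, 3))
            s = rng.uniform(0.05, 0.4, (2, 3))
            a = np.concatenate([c[0], s[0]])
            b = np.concatenate([c[1], s[1]])
            val = giou_loss(a, b).item()
            assert 0.0 <= val < 2.0
        outer = _corners_to_cs([0.1, 0.1, 0.1], [0.9, 0.9, 0.9])
        inner = _corners_to_cs([0.3, 0.3, 0.3], [0.5, 0.6, 0.7])
        iou = (0.2 * 0.3 * 0.4) / (0.8 ** 3)
        assert giou_loss(outer, inner).item() == pytest.approx(1 - iou, rel=1e-5)

    def test_analytic_matches_voxelized_oracle_on_200_random_pairs(self, rng):
        resolution = 64
        worst = 0.0
        for _ in range(200):
            c = rng.uniform(0.25, 0.75, (2, 3))
            s = rng.uniform(0.05, 0.45, (2, 3))
            a = np.concatenate([c[0], s[0]])
            b = np.concatenate([c[1], s[1]])
            analytic = giou_loss(a, b).item()
            voxel = voxelized_giou_oracle(a, b, resolution)
            worst = max(worst, abs(analytic - voxel))
        assert worst < 3.0 / resolution

    def test_oracle_is_symmetric_and_exact_for_identical_boxes(self):
        box = _corners_to_cs([0.2, 0.2, 0.2], [0.7, 0.6, 0.5])
        assert voxelized_giou_oracle(box, box, 20) == pytest.approx(0.0)
        a = _corners_to_cs([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        b = _corners_to_cs([0.3, 0.1, 0.2], [0.8, 0.4, 0.9])
        assert voxelized_giou_oracle(a, b, 50) == pytest.approx(
            voxelized_giou_oracle(b, a, 50))

    def test_gradients_flow_through_giou(self, rng):
        pred = Tensor(rng.uniform(0.3, 0.7, (2, 6)).astype(np.float32),
                      requires_grad=True)
        tgt = rng.uniform(0.3, 0.7, (2, 6)).astype(np.float32)
        giou_loss(pred, tgt).backward()
        assert pred.grad is not None and np.isfinite(pred.grad).all()


class TestTotalLoss:
    def test_perfect_predictions_give_zero(self):
        targets = np.array([[1, 0, 1, 0, 0, 1]], dtype=float)
        logits = (2 * targets - 1) * 60.0
        boxes = np.tile(np.array([0.5, 0.5, 0.5, 0.2, 0.2, 0.2]), (1, 2))
        total, comps = total_loss(logits, targets, boxes, boxes.copy(), np.ones(6))
        assert total.item() == pytest.approx(0.0, abs=1e-5)

    def test_reduces_to_bce_when_boxes_perfect(self, rng):
        targets = (rng.random((3, 6)) < 0.5).astype(float)
        logits = rng.normal(size=(3, 6))
        boxes = np.tile(np.array([0.5, 0.5, 0.5, 0.2, 0.3, 0.25]), (3, 2))
        total, comps = total_loss(logits, targets, boxes, boxes.copy(), np.ones(6))
        bce = weighted_bce(logits, targets, np.ones(6)).item()
        assert total.item() == pytest.approx(bce, rel=1e-5)

    def test_total_equals_sum_of_components(self, rng):
        targets = (rng.random((4, 6)) < 0.5).astype(float)
        logits = rng.normal(size=(4, 6))
        pred = rng.uniform(0.2, 0.8, (4, 12))
        tgt = rng.uniform(0.2, 0.8, (4, 12))
        total, comps = total_loss(logits, targets, pred, tgt, np.ones(6))
        assert total.item() == pytest.approx(
            comps["bce"] + comps["l1"] + comps["giou"], rel=1e-6)
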