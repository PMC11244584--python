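import math

import numpy as np
import pytest

from conftest import random_box_pair
from safi.losses import (BoundingBox, BoxPair, PiouParams, attention_u,
                         ciou_loss, f, iou, l_piou, l_piou_v2, penalty_P,
                         piou, piou_v2_loss)
from safi.nn import Tensor

IDENT = BoxPair(BoundingBox(0, 0, 0, 2, 2), BoundingBox(0, 0, 0, 2, 2))
SHIFT = BoxPair(BoundingBox(0, 0, 0, 2, 2), BoundingBox(0, 1, 1, 3, 3))


class TestScalarChain:
    def test_iou_identical(self):
        assert iou(IDENT) == 1.0

    def test_iou_disjoint(self):
        pair = BoxPair(BoundingBox(0, 0, 0, 1, 1), BoundingBox(0, 5, 5, 6, 6))
        assert iou(pair) == 0.0

    def test_iou_hand_example(self):
        assert iou(SHIFT) == pytest.approx(1 / 7, rel=1e-12)

    def test_penalty_identical(self):
        assert penalty_P(IDENT) == 0.0

    def test_penalty_hand_example(self):
        assert penalty_P(SHIFT) == pytest.approx(0.5)

    def test_penalty_translation_invariant(self, rng):
        for _ in range(20):
            pair = random_box_pair(rng)
            dx, dy = rng.uniform(-50, 50, 2)
            moved = BoxPair(
                BoundingBox(0, pair.pred.x1 + dx, pair.pred.y1 + dy,
                            pair.pred.x2 + dx, pair.pred.y2 + dy),
                BoundingBox(0, pair.target.x1 + dx, pair.target.y1 + dy,
                            pair.target.x2 + dx, pair.target.y2 + dy))
            assert penalty_P(moved) == pytest.approx(penalty_P(pair), rel=1e-9)

    def test_penalty_zero_iff_coincide(self, rng):
        for _ in range(50):
            pair = random_box_pair(rng)
            same = (pair.pred.as_array() == pair.target.as_array()).all()
            assert (penalty_P(pair) == 0.0) == bool(same)

    def test_f_values(self):
        assert f(0) == 0.0
        assert f(1) == pytest.approx(1 - math.exp(-1))
        assert f(0.5) == pytest.approx(1 - math.exp(-0.25))
        assert f(-0.7) == f(0.7)  # even

    def test_piou_identical(self):
        assert piou(IDENT) == 1.0

    def test_piou_hand_example(self):
        assert piou(SHIFT) == pytest.approx(1 / 7 - (1 - math.exp(-0.25)), abs=1e-6)
        assert piou(SHIFT) == pytest.approx(-0.078342, abs=1e-6)

    def test_piou_far_separated_negative(self):
        pair = BoxPair(BoundingBox(0, 0, 0, 1, 1), BoundingBox(0, 50, 50, 51, 51))
        assert piou(pair) == pytest.approx(-f(penalty_P(pair)))
        assert piou(pair) < 0

    def test_l_piou_identical(self):
        assert l_piou(IDENT) == 0.0

    def test_l_piou_hand_example_both_forms(self):
        lhs = l_piou(SHIFT)
        rhs = (1 - 1 / 7) + f(0.5)  # L_IoU + f(P)
        assert lhs == pytest.approx(1.078342, abs=1e-6)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_attention_u(self):
        assert attention_u(0) == 0.0
        assert attention_u(1.1) == pytest.approx(3.3 * math.exp(-1.21), rel=1e-12)
        assert attention_u(1.1) == pytest.approx(0.984050, abs=1e-5)

    def test_attention_argmax(self):
        xs = np.linspace(0, 3, 30001)
        us = 3 * xs * np.exp(-xs * xs)
        assert xs[np.argmax(us)] == pytest.approx(1 / math.sqrt(2), abs=1e-3)

    def test_l_piou_v2_identical_zero(self):
        assert l_piou_v2(IDENT, PiouParams(1.1)) == 0.0

    def test_l_piou_v2_hand_chain(self):
        # exact chain: q = e^-P, u(lambda*q), loss = u * L_PIoU
        q = math.exp(-0.5)
        assert q == pytest.approx(0.606531, abs=1e-6)
        u = attention_u(1.1 * q)
        exact = u * ((1 - 1 / 7) + f(0.5))
        assert l_piou_v2(SHIFT, PiouParams(1.1)) == pytest.approx(exact, rel=1e-12)
        # and it agrees with the quoted hand arithmetic to ~1e-4
        assert u == pytest.approx(1.282511, abs=1e-4)
        assert l_piou_v2(SHIFT, PiouParams(1.1)) == pytest.approx(1.382988, abs=1e-4)

    def test_lambda_validation(self):
        with pytest.raises(ValueError):
            PiouParams(lambda_=-1.0)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            BoundingBox(0, 0, 0, 0, 2)


class TestBoundsAndProperties:
    def test_bounds_100k_pairs(self):
        from safi.losses import piou_loss, sample_box_pairs

        rng = np.random.default_rng(99)
        preds, tgts = sample_box_pairs(10**5, rng)
        l = piou_loss(Tensor(preds), tgts).data
        assert np.all(l >= 0.0) and np.all(l <= 2.0)
        p = 1.0 - l  # PIoU
        assert np.all(p >= -1.0) and np.all(p <= 1.0)
        # scalar-path spot checks agree and q stays in (0, 1]
        for _ in range(500):
            pair = random_box_pair(rng)
            assert -1.0 <= piou(pair) <= 1.0
            assert 0.0 <= l_piou(pair) <= 2.0
            assert 0.0 < math.exp(-penalty_P(pair)) <= 1.0

    def test_identity_two_forms_1e12(self, rng):
        for _ in range(200):
            pair = random_box_pair(rng)
            assert abs(l_piou(pair) - ((1 - iou(pair)) + f(penalty_P(pair)))) < 1e-12

    def test_zero_at_optimum_iff(self, rng):
        for _ in range(200):
            pair = random_box_pair(rng)
            v = l_piou_v2(pair)
            same = (pair.pred.as_array() == pair.target.as_array()).all()
            assert (v == 0.0) == bool(same)
            assert v >= 0.0

    def test_monotone_in_iou_at_fixed_P(self):
        # two constructions with identical P but different IoU:
        # translation by d (deltas d,d on y-edges) vs x2-only growth by 2d
        t = BoundingBox(0, 0.0, 0.0, 10.0, 10.0)
        for d in (1.0, 2.0, 4.0):
            trans = BoxPair(BoundingBox(0, 0, -d, 10, 10 - d), t)
            grow = BoxPair(BoundingBox(0, 0, 0, 10 + 2 * d, 10), t)
            assert penalty_P(trans) == pytest.approx(penalty_P(grow), rel=1e-12)
            assert iou(grow) > iou(trans)
            assert l_piou(grow) < l_piou(trans)


class TestBatchedLosses:
    def test_batched_matches_scalar(self, rng):
        pairs = [random_box_pair(rng) for _ in range(64)]
        preds = np.stack([p.pred.as_array() for p in pairs])
        tgts = np.stack([p.target.as_array() for p in pairs])
        out = piou_v2_loss(Tensor(preds), tgts).data
        ref = np.array([l_piou_v2(p) for p in pairs])
        assert np.allclose(out, ref, rtol=1e-5, atol=1e-7)

    def test_gradient_finite_difference_100_pairs(self, rng):
        pairs = [random_box_pair(rng) for _ in range(100)]
        preds = np.stack([p.pred.as_array() for p in pairs])
        tgts = np.stack([p.target.as_array() for p in pairs])
        # differentiate through the attention factor so finite differences of
        # the actual function apply (the detached default is a training choice)
        params = PiouParams(lambda_=1.1, detach_attention=False)
        pt = Tensor(preds.copy(), requires_grad=True)
        piou_v2_loss(pt, tgts, params).sum().backward()
        eps = 1e-6
        checked = 0
        for i in range(100):
            # skip pairs sitting on a kink of |.| / min / max (subgradients)
            if np.any(np.abs(preds[i] - tgts[i]) < 1e-3):
                continue
            iw = min(preds[i, 2], tgts[i, 2]) - max(preds[i, 0], tgts[i, 0])
            ih = min(preds[i, 3], tgts[i, 3]) - max(preds[i, 1], tgts[i, 1])
            if abs(iw) < 1e-3 or abs(ih) < 1e-3:
                continue
            checked += 1
            for j in range(4):
                pp = preds.copy()
                pp[i, j] += eps
                fp = piou_v2_loss(Tensor(pp), tgts, params).data.sum()
                pp[i, j] -= 2 * eps
                fm = piou_v2_loss(Tensor(pp), tgts, params).data.sum()
                num = (fp - fm) / (2 * eps)
                scale = max(abs(num), abs(pt.grad[i, j]), 1e-3)
                assert abs(pt.grad[i, j] - num) / scale < 1e-4
        assert checked >= 50

    def test_ciou_perfect_zero(self):
        b = np.array([[0.0, 0.0, 5.0, 5.0]])
        assert ciou_loss(Tensor(b), b).data[0] == pytest.approx(0.0, abs=1e-6)

    def test_ciou_decreases_with_overlap(self):
        t = np.array([[0.0, 0.0, 10.0, 10.0]])
        near = ciou_loss(Tensor(np.array([[1.0, 1.0, 11.0, 11.0]])), t).data[0]
        far = ciou_loss(Tensor(np.array([[20.0, 20.0, 30.0, 30.0]])), t).data[0]
        assert near < far

    def test_toy_descent_decreases(self):
        t = np.array([[20.0, 20.0, 60.0, 60.0]])
        pred = Tensor(np.array([[10.0, 15.0, 40.0, 45.0]]), requires_grad=True)
        losses = []
        for _ in range(100):
            loss = piou_v2_loss(pred, t).sum()
            losses.append(float(loss.data))
            pred.grad = None
            loss.backward()
            pred.data -= 20.0 * pred.grad
        assert losses[-1] < 0.1 * losses[0]
        assert losses[-1] == pytest.approx(0.0, abs=0.05)
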