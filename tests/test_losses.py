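"""The combined detector loss against hand-computed oracles.

Expected values were computed by hand from the definitions:
mean binary cross-entropy for objectness, mean categorical cross-entropy
for classification, per-box summed squared coordinate error for keypoints.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from murimetry.errors import ConfigError
from murimetry.losses import (LossBatch, class_loss, class_loss_grad,
                              keypoint_loss, keypoint_loss_grad,
                              objectness_loss, objectness_loss_grad,
                              total_loss)

EPS = 1e-7


def make_batch(y=(1.0,), p=(0.5,), Y=None, P=None, pred=None, gt=None,
               visibility=None):
    n = len(y)
    if Y is None:
        Y = np.tile([1.0, 0.0], (n, 1))
    if P is None:
        P = np.tile([0.5, 0.5], (n, 1))
    if pred is None:
        pred = np.zeros((n, 1, 2))
    if gt is None:
        gt = np.zeros((n, 1, 2))
    return LossBatch(y=np.array(y), p=np.array(p), Y=Y, P=P,
                     pred=pred, gt=gt, visibility=visibility)


class TestObjectnessLoss:
    def test_perfect_prediction_is_zero_at_clamp(self):
        b = make_batch(y=[1.0], p=[1.0 - EPS])
        assert objectness_loss(b) == pytest.approx(0.0, abs=1e-6)

    def test_hand_computed_value(self):
        b = make_batch(y=[1.0, 0.0], p=[0.8, 0.3])
        expected = -0.5 * (np.log(0.8) + np.log(0.7))  # 0.28991
        assert objectness_loss(b) == pytest.approx(expected, abs=1e-9)
        assert objectness_loss(b) == pytest.approx(0.28991, abs=1e-5)

    @given(st.lists(st.tuples(st.integers(0, 1),
                              st.floats(0.01, 0.99)), min_size=1, max_size=8))
    def test_label_flip_symmetry(self, pairs):
        y = np.array([a for a, _ in pairs], dtype=float)
        p = np.array([b for _, b in pairs])
        a = objectness_loss(make_batch(y=y, p=p))
        b = objectness_loss(make_batch(y=1 - y, p=1 - p))
        assert a == pytest.approx(b, rel=1e-12)

    def test_empty_batch_rejected(self):
        with pytest.raises(ConfigError):
            make_batch(y=[], p=[])


class TestClassLoss:
    def test_one_hot_match_is_zero(self):
        b = make_batch(Y=np.array([[1.0, 0.0]]),
                       P=np.array([[1.0 - EPS, EPS]]))
        assert class_loss(b) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("C", [2, 3, 5])
    def test_uniform_probabilities_give_log_C(self, C):
        Y = np.eye(C)[[0] * 4]
        P = np.full((4, C), 1.0 / C)
        b = make_batch(y=[1.0] * 4, p=[0.5] * 4, Y=Y, P=P)
        assert class_loss(b) == pytest.approx(np.log(C), abs=1e-9)

    def test_hand_computed_value(self):
        b = make_batch(y=[1.0, 0.0], p=[0.5, 0.5],
                       Y=np.array([[1.0, 0.0], [0.0, 1.0]]),
                       P=np.array([[0.9, 0.1], [0.2, 0.8]]))
        expected = -0.5 * (np.log(0.9) + np.log(0.8))  # 0.16425
        assert class_loss(b) == pytest.approx(expected, abs=1e-9)
        assert class_loss(b) == pytest.approx(0.16425, abs=1e-5)

    def test_matches_objectness_for_two_classes(self, rng):
        # internal consistency: binary CE == categorical CE with P=[1-p, p]
        y = rng.integers(0, 2, 6).astype(float)
        p = rng.uniform(0.05, 0.95, 6)
        Y = np.column_stack([1 - y, y])
        P = np.column_stack([1 - p, p])
        b = make_batch(y=y, p=p, Y=Y, P=P)
        assert objectness_loss(b) == pytest.approx(class_loss(b), rel=1e-9)


class TestKeypointLoss:
    def test_zero_when_prediction_matches(self):
        b = make_batch(pred=np.ones((1, 3, 2)), gt=np.ones((1, 3, 2)))
        assert keypoint_loss(b) == 0.0

    def test_three_four_five_offset(self):
        b = make_batch(pred=np.array([[[3.0, 4.0]]]), gt=np.zeros((1, 1, 2)))
        assert keypoint_loss(b) == pytest.approx(25.0, abs=1e-12)

    def test_hand_computed_two_box_value(self):
        pred = np.array([[[1.0, 0.0], [0.0, 1.0]],
                         [[0.0, 0.0], [2.0, 0.0]]])
        gt = np.zeros((2, 2, 2))
        b = make_batch(y=[1.0, 1.0], p=[0.5, 0.5], pred=pred, gt=gt)
        assert keypoint_loss(b) == pytest.approx(3.0, abs=1e-12)

    def test_invisible_keypoints_excluded_divisor_unchanged(self):
        pred = np.array([[[3.0, 4.0], [10.0, 0.0]]])
        gt = np.zeros((1, 2, 2))
        vis = np.array([[True, False]])
        b = make_batch(pred=pred, gt=gt, visibility=vis)
        assert keypoint_loss(b) == pytest.approx(25.0)


class TestTotalLoss:
    def test_sum_of_worked_examples(self):
        b = make_batch(y=[1.0, 0.0], p=[0.8, 0.3],
                       Y=np.array([[1.0, 0.0], [0.0, 1.0]]),
                       P=np.array([[0.9, 0.1], [0.2, 0.8]]),
                       pred=np.array([[[1.0, 0.0], [0.0, 1.0]],
                                      [[0.0, 0.0], [2.0, 0.0]]]),
                       gt=np.zeros((2, 2, 2)))
        expected = (-0.5 * (np.log(0.8) + np.log(0.7))
                    - 0.5 * (np.log(0.9) + np.log(0.8)) + 3.0)
        assert total_loss(b) == pytest.approx(expected, abs=1e-9)
        assert total_loss(b) == pytest.approx(3.45416, abs=1e-5)

    @given(st.integers(0, 1000))
    def test_additivity_on_random_batches(self, seed):
        rng = np.random.default_rng(seed)
        n, c, k = rng.integers(1, 5), rng.integers(2, 4), rng.integers(1, 4)
        P = rng.dirichlet(np.ones(c), n)
        Y = np.eye(c)[rng.integers(0, c, n)]
        b = make_batch(y=rng.integers(0, 2, n).astype(float),
                       p=rng.uniform(0.01, 0.99, n), Y=Y, P=P,
                       pred=rng.normal(size=(n, k, 2)),
                       gt=rng.normal(size=(n, k, 2)))
        assert total_loss(b) == pytest.approx(
            objectness_loss(b) + class_loss(b) + keypoint_loss(b), rel=1e-12)
        assert objectness_loss(b) >= 0
        assert class_loss(b) >= 0
        assert keypoint_loss(b) >= 0


def _numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g


class TestAnalyticGradients:
    """Finite-difference verification of each loss gradient."""

    def test_objectness_gradient(self, rng):
        b = make_batch(y=rng.integers(0, 2, 5).astype(float),
                       p=rng.uniform(0.1, 0.9, 5))
        num = _numeric_grad(lambda: objectness_loss(b), b.p)
        assert np.abs(objectness_loss_grad(b) - num).max() < 1e-4

    def test_class_gradient(self, rng):
        P = rng.dirichlet(np.ones(3), 4)
        Y = np.eye(3)[rng.integers(0, 3, 4)]
        b = make_batch(y=[1.0] * 4, p=[0.5] * 4, Y=Y, P=P)
        num = _numeric_grad(lambda: class_loss(b), b.P)
        assert np.abs(class_loss_grad(b) - num).max() < 1e-4

    def test_keypoint_gradient(self, rng):
        b = make_batch(pred=rng.normal(size=(2, 3, 2)),
                       gt=rng.normal(size=(2, 3, 2)),
                       y=[1.0, 0.0], p=[0.5, 0.5],
                       visibility=rng.random((2, 3)) > 0.3)
        num = _numeric_grad(lambda: keypoint_loss(b), b.pred)
        assert np.abs(keypoint_loss_grad(b) - num).max() < 1e-4
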