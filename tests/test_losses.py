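"""Loss and metric formulas: confusion counts, DSC, Tversky, cross-entropy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from multipath_unet import (
    ConfusionCounts,
    TverskyParams,
    combined_loss,
    confusion_counts,
    cross_entropy_loss,
    dice_similarity,
    per_class_dice,
    tversky_loss,
)
from multipath_unet.losses import combined_loss_and_grad


class TestConfusionCounts:
    def test_perfect_foreground_agreement(self):
        m = np.ones((10, 10))
        c = confusion_counts(m, m)
        assert (c.tp, c.fp, c.fn) == (100.0, 0.0, 0.0)

    def test_all_false_positives(self):
        pred, truth = np.ones((5, 5)), np.zeros((5, 5))
        c = confusion_counts(pred, truth)
        assert (c.tp, c.fp, c.fn) == (0.0, 25.0, 0.0)

    def test_four_pixel_enumeration(self):
        c = confusion_counts(np.array([1, 1, 0, 0]), np.array([1, 0, 1, 0]))
        assert (c.tp, c.fp, c.fn) == (1.0, 1.0, 1.0)

    def test_soft_counts_reduce_to_hard_on_binary_input(self, rng):
        pred = (rng.random((8, 8)) > 0.5).astype(float)
        truth = (rng.random((8, 8)) > 0.5).astype(float)
        c = confusion_counts(pred, truth)
        assert c.tp == ((pred == 1) & (truth == 1)).sum()
        assert c.fp == ((pred == 1) & (truth == 0)).sum()
        assert c.fn == ((pred == 0) & (truth == 1)).sum()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0)


class TestDice:
    def test_empty_vs_empty_is_one(self):
        assert dice_similarity(ConfusionCounts(0, 0, 0)) == 1.0

    def test_perfect_prediction_is_one(self):
        assert dice_similarity(ConfusionCounts(5, 0, 0)) == 1.0

    def test_hand_example(self):
        assert dice_similarity(ConfusionCounts(2, 1, 1)) == pytest.approx(
            2 / 3, abs=1e-4)

    @given(tp=st.floats(0, 1e4), fp=st.floats(0, 1e4), fn=st.floats(0, 1e4))
    @settings(derandomize=True, max_examples=200)
    def test_bounded_and_symmetric_in_fp_fn(self, tp, fp, fn):
        d = dice_similarity(ConfusionCounts(tp, fp, fn))
        assert 0.0 <= d <= 1.0
        # swapping FP and FN (prediction/truth exchange) leaves DSC unchanged
        assert d == pytest.approx(dice_similarity(ConfusionCounts(tp, fn, fp)),
                                  rel=1e-12)

    @given(tp=st.floats(0.1, 1e3), fp=st.floats(0, 1e3),
           extra=st.floats(0.01, 1e3))
    @settings(derandomize=True, max_examples=200)
    def test_monotone_decreasing_in_fp(self, tp, fp, extra):
        base = dice_similarity(ConfusionCounts(tp, fp, 0))
        worse = dice_similarity(ConfusionCounts(tp, fp + extra, 0))
        assert worse <= base

    def test_per_class_dice_treats_each_class_as_positive(self):
        pred = np.array([[0, 1], [1, 1]])
        truth = np.array([[0, 1], [0, 1]])
        bg, fg = per_class_dice(pred, truth)
        assert fg == pytest.approx(2 * 2 / (2 * 2 + 1 + 0))
        assert bg == pytest.approx(2 * 1 / (2 * 1 + 0 + 1))


class TestTversky:
    def test_perfect_prediction_zero_loss(self):
        m = np.ones((6, 6))
        assert tversky_loss(m, m) == pytest.approx(0.0)

    def test_hand_example_unsmoothed(self):
        # TP=2, FP=1, FN=1 at alpha=beta=0.5: 1 - 2/(2+0.5+0.5) = 1/3
        pred = np.array([1.0, 1.0, 1.0, 0.0])
        truth = np.array([1.0, 1.0, 0.0, 1.0])
        loss = tversky_loss(pred, truth, TverskyParams(0.5, 0.5, smooth=0.0))
        assert loss == pytest.approx(1 / 3)

    def test_balanced_weights_complement_smoothed_dice(self, rng):
        """At alpha = beta = 0.5, the Tversky loss equals one minus the
        smoothed DSC (smoothing constant doubled by the 2x rescaling)."""
        smooth = 1.0
        for _ in range(100):
            pred = rng.random((12, 12))
            truth = (rng.random((12, 12)) > 0.5).astype(float)
            c = confusion_counts(pred, truth)
            smoothed_dsc = (2 * c.tp + 2 * smooth) / (
                2 * c.tp + c.fp + c.fn + 2 * smooth)
            loss = tversky_loss(pred, truth,
                                TverskyParams(0.5, 0.5, smooth=smooth))
            assert abs(loss - (1.0 - smoothed_dsc)) < 1e-10


class TestCrossEntropy:
    def test_one_hot_match_is_near_zero(self):
        truth = np.array([[0, 1]])
        probs = np.stack([1.0 - truth, truth]).astype(float)  # (class, 1, 2)
        assert cross_entropy_loss(probs, truth) < 1e-5

    def test_uniform_prediction_is_ln2(self):
        probs = np.full((2, 3, 3), 0.5)
        truth = np.zeros((3, 3), dtype=int)
        assert cross_entropy_loss(probs, truth) == pytest.approx(np.log(2))

    def test_quarter_probability_contributes_ln4(self):
        probs = np.stack([np.full((2, 2), 0.75), np.full((2, 2), 0.25)])
        truth = np.ones((2, 2), dtype=int)
        assert cross_entropy_loss(probs, truth) == pytest.approx(-np.log(0.25))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.zeros((2, 4, 4)), np.zeros((3, 3), int))


class TestCombinedLoss:
    def test_equals_sum_of_components(self, rng):
        probs = rng.random((2, 2, 6, 6))
        probs /= probs.sum(axis=1, keepdims=True)
        truth = (rng.random((2, 6, 6)) > 0.5).astype(int)
        tv = np.mean([tversky_loss(probs[i, 1], truth[i]) for i in range(2)])
        expected = tv + cross_entropy_loss(probs, truth)
        assert combined_loss(probs, truth) == pytest.approx(expected)

    def test_perfect_prediction_is_near_zero(self):
        truth = (np.arange(16).reshape(4, 4) % 2)
        probs = np.stack([1.0 - truth, truth]).astype(float)
        # smooth>0 makes the Tversky term exactly 0 at perfect agreement
        assert combined_loss(probs, truth) < 1e-5

    def test_nonnegative_on_random_inputs(self, rng):
        for _ in range(20):
            probs = rng.random((1, 2, 5, 5))
            probs /= probs.sum(axis=1, keepdims=True)
            truth = (rng.random((1, 5, 5)) > 0.5).astype(int)
            assert combined_loss(probs, truth) >= 0.0

    def test_gradient_matches_value_function(self, rng):
        probs = rng.uniform(0.05, 0.95, (2, 2, 5, 5))
        probs /= probs.sum(axis=1, keepdims=True)
        truth = (rng.random((2, 5, 5)) > 0.5).astype(int)
        value, grad = combined_loss_and_grad(probs, truth)
        assert value == pytest.approx(combined_loss(probs, truth))
        eps = 1e-7
        check = np.random.default_rng(0)
        for _ in range(10):
            idx = tuple(check.integers(s) for s in probs.shape)
            old = probs[idx]
            probs[idx] = old + eps
            lp = combined_loss_and_grad(probs, truth)[0]
            probs[idx] = old - eps
            lm = combined_loss_and_grad(probs, truth)[0]
            probs[idx] = old
            assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)
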