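"""Focal loss, dice loss, the combined loss and their gradients."""

import numpy as np
import pytest

from viaphase.net.losses import (DICE_EPS, LossBatch, combined_loss,
                                 combined_loss_grad, dice_loss, focal_loss,
                                 softmax)
from viaphase.net.train import TrainConfig


def batch_from(probs, labels):
    probs = np.asarray(probs, dtype=float)
    return LossBatch.from_labels(probs, np.asarray(labels))


def perfect_batch(labels):
    labels = np.asarray(labels)
    probs = np.moveaxis(np.eye(3)[labels], -1, 1)
    return LossBatch(probs, probs.copy())


class TestFocal:
    def test_perfect_prediction_is_zero(self, rng):
        batch = perfect_batch(rng.integers(0, 3, (2, 6, 6)))
        assert focal_loss(batch, gamma=2.0) == pytest.approx(0.0, abs=1e-6)

    def test_single_pixel_half_probability(self):
        # -(1 - 0.5)^2 * log2(0.5) = 0.25
        probs = np.array([0.5, 0.3, 0.2]).reshape(1, 3, 1, 1)
        batch = batch_from(probs, np.zeros((1, 1, 1), int))
        assert focal_loss(batch, gamma=2.0) == pytest.approx(0.25)

    def test_gamma_zero_is_base2_cross_entropy(self, rng):
        probs = rng.dirichlet(np.ones(3), size=(2, 5, 5)).transpose(0, 3, 1, 2)
        labels = rng.integers(0, 3, (2, 5, 5))
        batch = batch_from(probs, labels)
        # independent cross-entropy oracle
        pt = np.take_along_axis(probs, labels[:, None], axis=1)[:, 0]
        ce = float(np.mean(-np.log2(np.clip(pt, 1e-7, 1.0))))
        assert focal_loss(batch, gamma=0.0) == pytest.approx(ce, abs=1e-12)

    def test_monotone_in_true_class_probability(self):
        """Lowering the true-class probability never lowers the loss."""
        for gamma in (0.0, 1.0, 2.0, 5.0):
            losses = []
            for p in (0.9, 0.7, 0.5, 0.3, 0.1):
                probs = np.array([p, 1 - p, 0.0]).reshape(1, 3, 1, 1)
                losses.append(focal_loss(batch_from(probs, np.zeros((1, 1, 1), int)),
                                         gamma))
            assert all(b >= a - 1e-12 for a, b in zip(losses, losses[1:]))

    def test_negative_gamma_rejected(self, rng):
        with pytest.raises(ValueError):
            focal_loss(perfect_batch(np.zeros((1, 2, 2), int)), gamma=-1)


class TestDice:
    def test_perfect_prediction_is_zero(self, rng):
        batch = perfect_batch(rng.integers(0, 3, (2, 4, 4)))
        assert dice_loss(batch, hard=True) == pytest.approx(0.0, abs=1e-6)
        assert dice_loss(batch, hard=False) == pytest.approx(0.0, abs=1e-6)

    def test_all_background_scene_scores_zero(self):
        """Classes absent from target AND prediction score 1 by the
        epsilon convention, so an all-background frame has zero loss."""
        batch = perfect_batch(np.full((1, 4, 4), 2, int))
        assert dice_loss(batch, hard=True) == pytest.approx(0.0, abs=1e-6)

    def test_hand_fixture_against_bruteforce(self):
        """2x2 frame, target all live, prediction 3 live + 1 background.

        Per-class tally: live TP=3, FN=1 -> 6/7; dead absent everywhere
        -> 1; background TP=0, FP=1 -> ~0.  Loss = 1 - (6/7 + 1 + 0)/3
        = 8/21.
        """
        labels = np.zeros((1, 2, 2), int)
        pred = np.zeros((1, 2, 2), int)
        pred[0, 1, 1] = 2
        probs = np.moveaxis(np.eye(3)[pred], -1, 1)
        batch = LossBatch(probs, np.moveaxis(np.eye(3)[labels], -1, 1))
        # independent brute-force per-class tally
        score = 0.0
        for c in range(3):
            tp = np.sum((pred == c) & (labels == c))
            fp = np.sum((pred == c) & (labels != c))
            fn = np.sum((pred != c) & (labels == c))
            score += (2 * tp + DICE_EPS) / (2 * tp + fp + fn + DICE_EPS)
        expected = 1.0 - score / 3.0
        got = dice_loss(batch, hard=True)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(8.0 / 21.0, abs=1e-5)

    def test_soft_equals_hard_on_onehot_probabilities(self, rng):
        batch = LossBatch(
            np.moveaxis(np.eye(3)[rng.integers(0, 3, (2, 4, 4))], -1, 1),
            np.moveaxis(np.eye(3)[rng.integers(0, 3, (2, 4, 4))], -1, 1))
        assert dice_loss(batch, hard=False) == pytest.approx(
            dice_loss(batch, hard=True), abs=1e-6)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(10):
            probs = rng.dirichlet(np.ones(3), size=(1, 6, 6)).transpose(0, 3, 1, 2)
            batch = batch_from(probs, rng.integers(0, 3, (1, 6, 6)))
            for hard in (True, False):
                assert 0.0 <= dice_loss(batch, hard=hard) <= 1.0


class TestCombined:
    def test_indicator_selection(self, rng):
        probs = rng.dirichlet(np.ones(3), size=(1, 4, 4)).transpose(0, 3, 1, 2)
        batch = batch_from(probs, rng.integers(0, 3, (1, 4, 4)))
        focal_only = TrainConfig(loss_alpha=1, loss_beta=0)
        dice_only = TrainConfig(loss_alpha=0, loss_beta=1)
        both = TrainConfig(loss_alpha=1, loss_beta=1)
        assert combined_loss(batch, focal_only) == pytest.approx(
            focal_loss(batch, focal_only.gamma))
        assert combined_loss(batch, dice_only) == pytest.approx(
            dice_loss(batch, hard=True))
        assert combined_loss(batch, both) == pytest.approx(
            focal_loss(batch, both.gamma) + dice_loss(batch, hard=True))

    def test_both_indicators_zero_rejected(self, rng):
        with pytest.raises(ValueError):
            TrainConfig(loss_alpha=0, loss_beta=0)

    def test_perfect_prediction_zero_for_any_indicators(self, rng):
        batch = perfect_batch(rng.integers(0, 3, (1, 4, 4)))
        for a, b in ((1, 0), (0, 1), (1, 1)):
            assert combined_loss(batch, TrainConfig(loss_alpha=a, loss_beta=b)) \
                == pytest.approx(0.0, abs=1e-6)


class TestGradients:
    @pytest.mark.parametrize("alpha,beta", [(1, 0), (0, 1), (1, 1)])
    def test_gradient_matches_numerical(self, rng, alpha, beta):
        logits = rng.normal(size=(2, 3, 4, 4))
        labels = rng.integers(0, 3, (2, 4, 4))
        onehot = np.moveaxis(np.eye(3)[labels], -1, 1)
        value, dz = combined_loss_grad(logits, onehot, 2.0, alpha, beta)
        eps = 1e-7
        for _ in range(8):
            idx = tuple(int(rng.integers(0, s)) for s in logits.shape)
            lp = logits.copy(); lp[idx] += eps
            lm = logits.copy(); lm[idx] -= eps
            vp, _ = combined_loss_grad(lp, onehot, 2.0, alpha, beta)
            vm, _ = combined_loss_grad(lm, onehot, 2.0, alpha, beta)
            num = (vp - vm) / (2 * eps)
            assert dz[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)

    def test_value_consistent_with_loss_functions(self, rng):
        logits = rng.normal(size=(1, 3, 5, 5))
        labels = rng.integers(0, 3, (1, 5, 5))
        onehot = np.moveaxis(np.eye(3)[labels], -1, 1)
        probs = softmax(logits)
        batch = LossBatch(probs, onehot)
        v_focal, _ = combined_loss_grad(logits, onehot, 2.0, 1, 0)
        assert v_focal == pytest.approx(focal_loss(batch, 2.0))
        v_dice, _ = combined_loss_grad(logits, onehot, 2.0, 0, 1)
        assert v_dice == pytest.approx(dice_loss(batch, hard=False))


class TestLossBatchValidation:
    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            LossBatch(np.ones((1, 3, 2, 2)) / 3, np.ones((1, 3, 2, 3)))

    def test_non_simplex_probs(self):
        bad = np.full((1, 3, 2, 2), 0.5)
        onehot = np.moveaxis(np.eye(3)[np.zeros((1, 2, 2), int)], -1, 1)
        with pytest.raises(ValueError):
            LossBatch(bad, onehot)

    def test_non_onehot_target(self):
        probs = np.full((1, 3, 2, 2), 1 / 3)
        bad = np.full((1, 3, 2, 2), 1 / 3)
        with pytest.raises(ValueError):
            LossBatch(probs, bad)
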