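"""Focal and dice losses for three-class viability segmentation.

The focal loss is the class-probability-weighted cross entropy

    L = -(1/B) sum_i (1/MN) sum_x [1 - y_i(x)^T p_i(x)]^gamma
                                  * y_i(x)^T log2 p_i(x),

with the logarithm in base 2 (a constant 1/ln 2 factor relative to the
natural-log convention of most libraries) and probabilities clipped to
[1e-7, 1] before the log.  The dice loss averages per-class overlap
scores over the three classes, counting TP/FP/FN across the whole batch
(micro), with an epsilon so that a class absent from both target and
prediction scores a perfect 1:

    L = 1 - (1/3) sum_c (2 TP_c + eps) / (2 TP_c + FP_c + FN_c + eps).

``dice_loss`` offers a hard mode (argmax labels, used for reporting) and
a soft mode (probability mass, differentiable, used in the training
gradient).  The combined loss is alpha * focal + beta * dice with binary
indicators alpha, beta.

Gradient helpers return d(loss)/d(logits) through the softmax; they are
verified against numerical differentiation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PROB_FLOOR = 1e-7
DICE_EPS = 1e-6
_LN2 = np.log(2.0)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class LossBatch:
    """A batch of predictions and one-hot targets, both (B, 3, H, W)."""

    probs: np.ndarray
    onehot: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.onehot = np.asarray(self.onehot, dtype=np.float64)
        if self.probs.shape != self.onehot.shape:
            raise ValueError("probs and onehot shapes differ")
        if self.probs.ndim != 4 or self.probs.shape[1] != 3:
            raise ValueError("expected shape (B, 3, H, W)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-5):
            raise ValueError("probabilities must sum to 1 per pixel")
        if np.any(self.probs < -1e-12):
            raise ValueError("probabilities must be non-negative")
        s = self.onehot.sum(axis=1)
        if not (np.array_equal(np.unique(self.onehot), [0.0, 1.0])
                or np.array_equal(np.unique(self.onehot), [1.0])
                or np.array_equal(np.unique(self.onehot), [0.0])):
            raise ValueError("targets must be one-hot (0/1 entries)")
        if not np.allclose(s, 1.0):
            raise ValueError("targets must be one-hot (sum to 1 per pixel)")

    @classmethod
    def from_labels(cls, probs: np.ndarray, labels: np.ndarray) -> "LossBatch":
        labels = np.asarray(labels)
        onehot = np.moveaxis(np.eye(3)[labels], -1, 1)
        return cls(probs, onehot)


def focal_loss(batch: LossBatch, gamma: float = 2.0) -> float:
    """Mean focal loss (base-2 log). gamma=0 reduces to cross entropy."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    pt = np.clip((batch.probs * batch.onehot).sum(axis=1), PROB_FLOOR, 1.0)
    per_pixel = -((1.0 - pt) ** gamma) * (np.log(pt) / _LN2)
    return float(per_pixel.mean())


def dice_loss(batch: LossBatch, hard: bool = True) -> float:
    """Macro-averaged dice loss over classes, micro counts over the batch."""
    if hard:
        pred = np.argmax(batch.probs, axis=1)
        true = np.argmax(batch.onehot, axis=1)
        score = 0.0
        for c in range(3):
            tp = float(((pred == c) & (true == c)).sum())
            fp = float(((pred == c) & (true != c)).sum())
            fn = float(((pred != c) & (true == c)).sum())
            score += (2 * tp + DICE_EPS) / (2 * tp + fp + fn + DICE_EPS)
        return float(1.0 - score / 3.0)
    # soft: 2 TP_c + FP_c + FN_c == sum(p_c) + sum(y_c)
    tp = (batch.probs * batch.onehot).sum(axis=(0, 2, 3))
    denom = batch.probs.sum(axis=(0, 2, 3)) + batch.onehot.sum(axis=(0, 2, 3))
    score = (2 * tp + DICE_EPS) / (denom + DICE_EPS)
    return float(1.0 - score.mean())


def combined_loss(batch: LossBatch, cfg) -> float:
    """alpha * focal + beta * dice with the config's indicator weights."""
    alpha, beta = int(cfg.loss_alpha), int(cfg.loss_beta)
    if alpha not in (0, 1) or beta not in (0, 1):
        raise ValueError("loss_alpha and loss_beta must be 0 or 1")
    if alpha == 0 and beta == 0:
        raise ValueError("at least one of loss_alpha, loss_beta must be 1")
    total = 0.0
    if alpha:
        total += focal_loss(batch, cfg.gamma)
    if beta:
        total += dice_loss(batch, hard=getattr(cfg, "dice_hard_report", True))
    return total


# ---------------------------------------------------------------------------
# gradients through the softmax (training path; soft dice for beta)


def combined_loss_grad(logits: np.ndarray, onehot: np.ndarray, gamma: float,
                       alpha: int, beta: int) -> tuple[float, np.ndarray]:
    """Loss value and d(loss)/d(logits) for alpha*focal + beta*soft-dice."""
    probs = softmax(logits)
    onehot = np.asarray(onehot, dtype=probs.dtype)
    g = np.zeros_like(probs)  # dL/dp
    value = 0.0
    n = probs.shape[0] * probs.shape[2] * probs.shape[3]

    if alpha:
        pt_raw = (probs * onehot).sum(axis=1)
        pt = np.clip(pt_raw, PROB_FLOOR, 1.0)
        log2pt = np.log(pt) / _LN2
        value += float((-((1.0 - pt) ** gamma) * log2pt).mean())
        if gamma == 0:
            dl_dpt = -1.0 / (pt * _LN2)
        else:
            dl_dpt = (gamma * (1.0 - pt) ** (gamma - 1) * log2pt
                      - (1.0 - pt) ** gamma / (pt * _LN2))
        dl_dpt = dl_dpt / n
        dl_dpt[(pt_raw < PROB_FLOOR) | (pt_raw > 1.0)] = 0.0  # clip region
        g += onehot * dl_dpt[:, None]

    if beta:
        tp = (probs * onehot).sum(axis=(0, 2, 3))
        denom = probs.sum(axis=(0, 2, 3)) + onehot.sum(axis=(0, 2, 3))
        num_c = 2 * tp + DICE_EPS
        den_c = denom + DICE_EPS
        value += float(1.0 - (num_c / den_c).mean())
        # d score_c / d p_c(x) = (2 y_c(x) den_c - num_c) / den_c^2
        dl_dp = -(2 * onehot * den_c[None, :, None, None]
                  - num_c[None, :, None, None]) / (3.0 * den_c[None, :, None, None] ** 2)
        g += dl_dp

    dz = probs * (g - (g * probs).sum(axis=1, keepdims=True))
    return value, dz
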