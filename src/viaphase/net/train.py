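"""Training loop, plateau learning-rate schedule and inference.

Training minimises the combined focal(+dice) loss with Adam
(beta1 = 0.9, beta2 = 0.999, eps = 1e-7), starting from lr = 5e-4 and
multiplying the learning rate by 0.8 whenever the validation loss has
not decreased for ``plateau_patience`` epochs.  The validation loss is
computed on the whole validation partition at the end of every epoch and
the weights with the lowest validation loss are kept.  The full-scale
profile of the assay (512 x 512 patches, batch 14 or 4, 100 epochs,
B3/B7-like encoders) is configurable but the defaults are the desk-scale
profile: tiny encoder, 128 x 128 patches, batch 8, 30 epochs.

Network inputs are normalized identically in training and in
:func:`predict`: by default a fixed affine map that preserves the
quantitative phase scale (see :func:`standardize`), with per-image
z-scoring available as an option for non-quantitative inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..ground_truth import SemanticMap
from ..optics import PhaseMap
from .augment import augment_patch
from .losses import combined_loss_grad, softmax
from .model import SegmentationModel, make_optimizer
from .split import SequenceSplit


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of the segmentation training run."""

    gamma: float = 2.0
    loss_alpha: int = 1
    loss_beta: int = 0
    learning_rate: float = 5e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-7
    batch_size: int = 8
    patch_px: int = 128
    epochs: int = 30
    plateau_patience: int = 10
    lr_decay: float = 0.8
    seed: int = 0
    encoder_name: str = "tiny"
    normalization: str = "fixed"  # "fixed" (quantitative phase) or "zscore"
    augmentations: tuple = ("crop", "flip", "shift", "noise", "brightness")
    dice_hard_report: bool = True

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if int(self.loss_alpha) not in (0, 1) or int(self.loss_beta) not in (0, 1):
            raise ValueError("loss_alpha/loss_beta must be 0 or 1")
        if self.loss_alpha == 0 and self.loss_beta == 0:
            raise ValueError("loss_alpha and loss_beta cannot both be 0")
        for name in ("learning_rate", "lr_decay", "batch_size", "patch_px", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.normalization not in ("fixed", "zscore"):
            raise ValueError("normalization must be 'fixed' or 'zscore'")


class PlateauScheduler:
    """Multiply lr by ``factor`` after ``patience`` non-improving epochs."""

    def __init__(self, initial_lr: float, factor: float = 0.8, patience: int = 10):
        self.lr = initial_lr
        self.factor = factor
        self.patience = patience
        self.best = np.inf
        self.wait = 0

    def step(self, val_loss: float) -> float:
        """Report an epoch's validation loss; returns the lr for the next epoch."""
        if val_loss < self.best:
            self.best = val_loss
            self.wait = 0
        else:
            self.wait += 1
            if self.wait >= self.patience:
                self.lr *= self.factor
                self.wait = 0
        return self.lr


@dataclass
class TrainResult:
    history: pd.DataFrame          # epoch, train_loss, val_loss, lr
    best_epoch: int                # 1-based epoch with lowest validation loss
    best_val_loss: float
    best_state: dict


#: fixed affine normalization for quantitative phase inputs: typical
#: cellular phase values span ~[0, 2.5] rad, mapped to roughly [-1, 2.3]
FIXED_OFFSET_RAD = 0.75
FIXED_SCALE_RAD = 0.75


def standardize(img: np.ndarray, mode: str = "fixed") -> np.ndarray:
    """Normalize a network input image.

    ``"fixed"`` applies a constant affine map, preserving the
    quantitative nature of phase: the same cell produces the same input
    regardless of what else is in the frame.  ``"zscore"`` standardizes
    per image (mean 0, sd 1), which adapts to arbitrary input scales
    but couples the prediction to scene composition - a frame's
    statistics change as cells die, shifting every nucleus relative to
    the decision boundary.  Constant images map to zeros under zscore.
    """
    img = np.asarray(img, dtype=np.float32)
    if mode == "fixed":
        return (img - FIXED_OFFSET_RAD) / FIXED_SCALE_RAD
    if np.ptp(img) == 0:
        return np.zeros_like(img)
    return (img - img.mean()) / img.std()


def _onehot(labels: np.ndarray) -> np.ndarray:
    return np.moveaxis(np.eye(3, dtype=np.float32)[labels], -1, 1)


def train(model: SegmentationModel, dataset: dict, split: SequenceSplit,
          cfg: TrainConfig) -> TrainResult:
    """Train ``model`` on a sequence-keyed dataset.

    ``dataset`` maps sequence id -> list of (image, label_map) frames;
    the split's partitions select sequences.  Returns the training
    history and restores the model to its best-validation weights.
    """
    train_frames = [fr for sid in split.train for fr in dataset[sid]]
    val_frames = [fr for sid in split.validation for fr in dataset[sid]]
    if not train_frames or not val_frames:
        raise ValueError("train and validation partitions must be non-empty")

    rng = np.random.default_rng(cfg.seed)
    model.normalization = cfg.normalization
    opt = make_optimizer(model, cfg)
    sched = PlateauScheduler(cfg.learning_rate, cfg.lr_decay, cfg.plateau_patience)
    alpha, beta = int(cfg.loss_alpha), int(cfg.loss_beta)

    best_val, best_epoch, best_state = np.inf, -1, None
    rows = []
    for epoch in range(1, cfg.epochs + 1):
        lr_this_epoch = sched.lr
        opt.lr = lr_this_epoch
        order = rng.permutation(len(train_frames))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xs, ys = [], []
            for i in idx:
                img, lab = augment_patch(*train_frames[i], cfg, rng)
                xs.append(standardize(img, cfg.normalization))
                ys.append(np.clip(lab, 0, 2).astype(np.int64))
            x = np.stack(xs)[:, None].astype(np.float32)
            y = _onehot(np.stack(ys))
            logits = model.forward(x, train=True)
            value, dz = combined_loss_grad(logits.astype(np.float64), y,
                                           cfg.gamma, alpha, beta)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {value}")
            opt.zero_grad()
            model.backward(dz.astype(np.float32))
            opt.step()
            epoch_losses.append(value)
        train_loss = float(np.mean(epoch_losses))
        val_loss = evaluate_loss(model, val_frames, cfg)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        rows.append({"epoch": epoch, "train_loss": train_loss,
                     "val_loss": val_loss, "lr": lr_this_epoch})
        if val_loss < best_val:
            best_val, best_epoch = val_loss, epoch
            best_state = model.state_dict()
        sched.step(val_loss)

    model.load_state_dict(best_state)
    model.trained = True
    return TrainResult(history=pd.DataFrame(rows), best_epoch=best_epoch,
                       best_val_loss=float(best_val), best_state=best_state)


def evaluate_loss(model: SegmentationModel, frames, cfg: TrainConfig) -> float:
    """Combined loss over a list of (image, label_map) frames (eval mode)."""
    total, n = 0.0, 0
    for img, lab in frames:
        x = standardize(_crop_to_divisor(img, model.downsample_factor),
                        cfg.normalization)
        lab = _crop_to_divisor(lab, model.downsample_factor)
        logits = model.forward(x[None, None].astype(np.float32), train=False)
        y = _onehot(np.asarray(lab, dtype=np.int64)[None])
        value, _ = combined_loss_grad(logits.astype(np.float64), y,
                                      cfg.gamma, int(cfg.loss_alpha),
                                      int(cfg.loss_beta))
        total += value
        n += 1
    return total / n


def _crop_to_divisor(arr: np.ndarray, d: int) -> np.ndarray:
    h, w = arr.shape[:2]
    return arr[:(h // d) * d, :(w // d) * d]


def predict(model: SegmentationModel, pm, tile_px: int | None = None,
            ) -> tuple[np.ndarray, SemanticMap]:
    """Run inference on a phase map (or bare 2-D array).

    Returns per-pixel class probabilities (3, H, W) and the argmax
    semantic map.  Images whose sides exceed ``tile_px`` are processed in
    half-overlapping tiles whose logits are averaged; otherwise a single
    padded forward pass is used.  Sides not divisible by the model's
    downsampling factor are reflect-padded and cropped back.
    """
    if not model.trained:
        raise RuntimeError("model has not been trained or loaded")
    img = pm.phase if isinstance(pm, PhaseMap) else np.asarray(pm)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    x = standardize(img, getattr(model, "normalization", "fixed"))
    h, w = x.shape
    d = model.downsample_factor

    if tile_px is not None and (h > tile_px or w > tile_px):
        logits = _tiled_logits(model, x, tile_px)
    else:
        ph = (d - h % d) % d
        pw = (d - w % d) % d
        xp = np.pad(x, ((0, ph), (0, pw)), mode="reflect") if (ph or pw) else x
        logits = model.forward(xp[None, None].astype(np.float32), train=False)[0]
        logits = logits[:, :h, :w]
    probs = softmax(logits.astype(np.float64), axis=0)
    labels = np.argmax(probs, axis=0).astype(np.uint8)
    return probs, SemanticMap(labels)


def _tiled_logits(model: SegmentationModel, x: np.ndarray, tile: int) -> np.ndarray:
    d = model.downsample_factor
    tile = (tile // d) * d
    h, w = x.shape
    step = tile // 2
    acc = np.zeros((3, h, w))
    wgt = np.zeros((h, w))
    r_starts = sorted({min(r, max(0, h - tile)) for r in range(0, h, step)})
    c_starts = sorted({min(c, max(0, w - tile)) for c in range(0, w, step)})
    for r0 in r_starts:
        for c0 in c_starts:
            r1, c1 = min(r0 + tile, h), min(c0 + tile, w)
            patch = x[r0:r1, c0:c1]
            ph = (d - patch.shape[0] % d) % d
            pw = (d - patch.shape[1] % d) % d
            if ph or pw:
                patch = np.pad(patch, ((0, ph), (0, pw)), mode="reflect")
            lg = model.forward(patch[None, None].astype(np.float32),
                               train=False)[0]
            acc[:, r0:r1, c0:c1] += lg[:, :r1 - r0, :c1 - c0]
            wgt[r0:r1, c0:c1] += 1.0
    return acc / wgt[None]
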