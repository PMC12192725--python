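"""Compound segmentation loss: 0.5 x binary cross-entropy + Dice loss.

The Dice *coefficient* is the smoothed overlap ratio
``(2 sum(p*y) + eps) / (sum p + sum y + eps)``; the loss term is
``1 - coefficient`` so that better overlap lowers the objective, and the
smoothing constant eps keeps the ratio finite on empty masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = ["LossConfig", "dice_coefficient", "combined_loss", "combined_loss_t"]

CLAMP = 1e-7  # probability clamp applied before the BCE logarithms


@dataclass(frozen=True)
class LossConfig:
    bce_weight: float = 0.5
    epsilon: float = 1.0

    def __post_init__(self):
        if self.bce_weight < 0:
            raise ValueError("bce_weight must be nonnegative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def _validate(pred: np.ndarray, target: np.ndarray):
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    if pred.min() < 0 or pred.max() > 1:
        raise ValueError("pred must be per-pixel probabilities in [0, 1]")
    if not np.isin(np.unique(target), (0, 1)).all():
        raise ValueError("target must be a binary mask")


def dice_coefficient(pred, target, epsilon: float = 1.0) -> float:
    """Smoothed Dice overlap between probabilities and a binary mask."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    _validate(pred, target)
    inter = float((pred * target).sum())
    return (2.0 * inter + epsilon) / (float(pred.sum() + target.sum()) + epsilon)


def combined_loss(pred, target, config: LossConfig = LossConfig()) -> float:
    """0.5*BCE + (1 - Dice) on plain arrays (evaluation path)."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    _validate(pred, target)
    p = np.clip(pred, CLAMP, 1.0 - CLAMP)
    bce = float(-(target * np.log(p) + (1 - target) * np.log(1 - p)).mean())
    dice = dice_coefficient(pred, target, config.epsilon)
    return config.bce_weight * bce + (1.0 - dice)


def combined_loss_t(
    probs: Tensor, target: np.ndarray, config: LossConfig = LossConfig()
) -> Tensor:
    """Tape-recorded loss on predicted probabilities (training path)."""
    y = Tensor(np.asarray(target, dtype=probs.dtype))
    p = probs.clip(CLAMP, 1.0 - CLAMP)
    bce = -(y * p.log() + (1.0 - y) * (1.0 - p).log()).mean()
    eps = config.epsilon
    inter = (probs * y).sum()
    dice = (2.0 * inter + eps) / (probs.sum() + y.sum() + eps)
    return bce * config.bce_weight + (1.0 - dice)
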