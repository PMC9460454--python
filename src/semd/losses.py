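"""Training objective: cross-entropy plus soft-Dice loss.

For per-pixel class probabilities p (after softmax) and one-hot targets y:

* cross-entropy: CE = −(1/N) Σ_n Σ_c y_{n,c} log p_{n,c}, with N the number
  of pixels in the batch;
* soft Dice per class: D_c = 2 Σ_n y p / (Σ_n y² + Σ_n p²), averaged over
  classes present-or-predicted; Dice loss = 1 − mean_c D_c;
* combined = CE + Dice loss.

A perfect one-hot prediction gives CE = 0 and Dice = 1, hence loss 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from . import nn
from .nn import Tensor

_EPS = 1e-7
_SMOOTH = 1e-6


@dataclass(frozen=True)
class LossTerms:
    """cross_entropy ≥ 0; dice is the soft Dice coefficient in [0, 1];
    combined = cross_entropy + (1 − dice)."""

    cross_entropy: float
    dice: float
    combined: float


def one_hot(mask: np.ndarray, num_classes: int) -> np.ndarray:
    """B×H×W integer mask → B×C×H×W one-hot float32."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() >= num_classes:
        raise ValueError(f"mask labels must lie in [0, {num_classes})")
    eye = np.eye(num_classes, dtype=np.float32)
    return np.moveaxis(eye[mask], -1, 1)


def combined_loss(probs: Union[Tensor, np.ndarray],
                  gt_onehot: np.ndarray) -> tuple[Tensor, LossTerms]:
    """Differentiable CE + (1 − soft Dice) on class probabilities.

    `probs` must lie on the per-pixel probability simplex (B×C×H×W);
    `gt_onehot` is the matching one-hot target.  Returns the scalar loss
    tensor (for backward) and a float summary of its terms.
    """
    if not isinstance(probs, Tensor):
        probs = Tensor(probs)
    y = np.asarray(gt_onehot, dtype=np.float32)
    if probs.shape != y.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs target {y.shape}")
    pdata = probs.data
    if pdata.min() < -1e-5 or pdata.max() > 1 + 1e-5:
        raise ValueError("probs must lie in [0, 1] — apply softmax first")

    b, c = probs.shape[0], probs.shape[1]
    n_pix = pdata.size // c
    yt = Tensor(y)

    ce = -(yt * nn.log(probs, eps=_EPS)).sum() * (1.0 / n_pix)

    # soft Dice per class over the whole batch
    axes = (0, 2, 3)
    inter = (yt * probs).sum(axis=axes)
    denom = Tensor((y * y).sum(axis=axes)) + (probs * probs).sum(axis=axes)
    dice_per_class = (2.0 * inter + _SMOOTH) / (denom + _SMOOTH)
    dice = dice_per_class.mean()

    loss = ce + (1.0 - dice)
    terms = LossTerms(float(ce.data), float(dice.data), float(loss.data))
    return loss, terms


def segmentation_loss(logits: Tensor, mask: np.ndarray) -> tuple[Tensor, LossTerms]:
    """Convenience wrapper: softmax the logits, one-hot the mask, combine."""
    probs = nn.softmax(logits, axis=1)
    return combined_loss(probs, one_hot(mask, logits.shape[1]))
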