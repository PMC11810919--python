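"""Training losses for binary segmentation under extreme class imbalance.

With the gallbladder occupying roughly half a percent of the pixels, plain
cross-entropy is dominated by the background class; the soft Dice loss

    L = 1 - (2 * sum(p_i * g_i) + eps) / (sum(p_i) + sum(g_i) + eps)

measures overlap directly and is the default training objective.  Binary
cross-entropy is provided as the comparator.  Both are computed per image;
batch training averages per-image losses (see :mod:`mcaunet.nn`), which keeps
the per-sample imbalance semantics instead of pooling pixels across a batch.
"""

from __future__ import annotations

from enum import Enum

import numpy as np


class Loss(str, Enum):
    DICE = "dice"
    BCE = "bce"


def _check_pair(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return pred, truth


def dice_loss(pred, truth, eps: float = 1e-6) -> float:
    """Soft Dice loss on one prediction/truth pair; value in [0, 1).

    ``pred`` holds per-pixel foreground probabilities, ``truth`` binary
    labels; ``eps`` is the small positive smoothing constant that guards the
    denominator.
    """
    if not 0 < eps <= 1:
        raise ValueError("eps must lie in (0, 1]")
    p, g = _check_pair(pred, truth)
    num = 2.0 * (p * g).sum() + eps
    den = p.sum() + g.sum() + eps
    return float(1.0 - num / den)


def bce_loss(pred, truth, clamp: float = 1e-7) -> float:
    """Mean binary cross-entropy; probabilities are clamped to
    [clamp, 1 - clamp] before the logarithms."""
    p, g = _check_pair(pred, truth)
    p = np.clip(p, clamp, 1.0 - clamp)
    return float(-(g * np.log(p) + (1.0 - g) * np.log(1.0 - p)).mean())
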