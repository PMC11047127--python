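"""Compound segmentation loss: weighted multi-class Dice plus categorical focal.

Both terms operate on a per-volume basis over a one-hot ground truth G
and a predicted probability map P with a trailing class axis.  The Dice
term is

    L_dice = 1 - (2 sum_c sum_i w_c G_ci P_ci + eps)
                 / (sum_c sum_i w_c G_ci + sum_c sum_i w_c P_ci + eps)

and the focal term

    L_focal = - sum_c sum_i G_ci log(P_ci) (1 - P_ci)^gamma

with gamma = 1 by default and all classes equally weighted.  The total
training loss is their sum.  Probabilities are clipped before the
logarithm so the focal term stays finite at hard 0/1 predictions.

Functions accept plain NumPy arrays (returning a float) or autodiff
Tensors (returning a Tensor, so gradients flow during training).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class LossValidationError(ValueError):
    pass


@dataclass
class LossConfig:
    """Loss hyperparameters.

    class_weights: one non-negative weight per class for the Dice term;
        ``None`` means equal weights.
    eps: Dice stabilizer preventing division by zero.
    gamma: focal modulation exponent (0 recovers cross-entropy).
    clip: probability clamp applied before logarithms.
    focal_reduction: ``"sum"`` (as defined) or ``"mean"`` over voxels.
    """

    class_weights: list[float] | None = None
    eps: float = 1e-5
    gamma: float = 1.0
    clip: float = 1e-7
    focal_reduction: str = "sum"

    def validate(self, n_classes: int) -> np.ndarray:
        if self.gamma < 0:
            raise LossValidationError("gamma must be >= 0")
        if self.eps <= 0:
            raise LossValidationError("eps must be > 0")
        if self.focal_reduction not in ("sum", "mean"):
            raise LossValidationError("focal_reduction must be 'sum' or 'mean'")
        if self.class_weights is None:
            return np.ones(n_classes)
        w = np.asarray(self.class_weights, dtype=float)
        if w.shape != (n_classes,):
            raise LossValidationError(
                f"need {n_classes} class weights, got shape {w.shape}")
        if np.any(w < 0):
            raise LossValidationError("class weights must be non-negative")
        return w


def _prepare(g, p):
    """Flatten to (voxels, classes); keep Tensors symbolic."""
    g_t = g if isinstance(g, Tensor) else Tensor(np.asarray(g, dtype=float))
    p_t = p if isinstance(p, Tensor) else Tensor(np.asarray(p, dtype=float))
    if g_t.shape != p_t.shape:
        raise LossValidationError(
            f"shape mismatch: G {g_t.shape} vs P {p_t.shape}")
    n_classes = g_t.shape[-1]
    g_t = ad.reshape(g_t, (-1, n_classes))
    p_t = ad.reshape(p_t, (-1, n_classes))
    return g_t, p_t, n_classes


def _maybe_float(value: Tensor, g, p):
    if isinstance(g, Tensor) or isinstance(p, Tensor):
        return value
    return value.item()


def dice_loss(g, p, cfg: LossConfig | None = None):
    """Weighted soft Dice loss in [0, 1]; 0 iff P == G."""
    cfg = cfg or LossConfig()
    g_t, p_t, k = _prepare(g, p)
    w = Tensor(cfg.validate(k))
    inter = ad.sum_(w * g_t * p_t)
    gsum = ad.sum_(w * g_t)
    psum = ad.sum_(w * p_t)
    loss = 1.0 - (2.0 * inter + cfg.eps) / (gsum + psum + cfg.eps)
    return _maybe_float(loss, g, p)


def focal_loss(g, p, cfg: LossConfig | None = None):
    """Categorical focal loss, summed (default) over voxels and classes."""
    cfg = cfg or LossConfig()
    g_t, p_t, k = _prepare(g, p)
    cfg.validate(k)
    p_c = ad.clip(p_t, cfg.clip, 1.0 - cfg.clip)
    per_entry = g_t * ad.log(p_c) * (1.0 - p_c) ** cfg.gamma
    loss = -ad.sum_(per_entry)
    if cfg.focal_reduction == "mean":
        loss = loss * (1.0 / g_t.shape[0])
    return _maybe_float(loss, g, p)


def total_loss(g, p, cfg: LossConfig | None = None):
    """Training loss: dice_loss + focal_loss, exactly additive."""
    cfg = cfg or LossConfig()
    d = dice_loss(g, p, cfg)
    f = focal_loss(g, p, cfg)
    return d + f
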