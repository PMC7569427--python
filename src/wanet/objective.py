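"""Combined cross-entropy + Dice objective for unbalanced vessel masks.

Vessel pixels are a small minority of a fundus image, so plain
cross-entropy is dominated by the background class. The training loss
therefore adds a smoothed Dice term on the vessel-probability channel:

    L = L_CE + L_Dice
    L_CE   = -sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ]
    L_Dice = 1 - (2 sum_i y_i p_i + k) / (sum_i y_i + sum_i p_i + k)

with smoothing k = 1.0 so the empty-mask case is well defined.
Cross-entropy is written as a sum over pixels; a mean reduction is
available via ``reduction`` (the trainer uses it so the CE:Dice balance
does not depend on patch size). Probabilities are clipped away from
{0, 1} before the logarithms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LossConfig:
    smooth: float = 1.0
    clip: float = 1e-7
    reduction: str = "sum"  # "sum" | "mean" (CE term only)

    def __post_init__(self) -> None:
        if self.smooth <= 0:
            raise ValueError("smooth must be > 0")
        if not (0 < self.clip < 0.5):
            raise ValueError("clip must lie in (0, 0.5)")
        if self.reduction not in ("sum", "mean"):
            raise ValueError("reduction must be 'sum' or 'mean'")


def _check(y_pred: np.ndarray, y_true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(y_pred, dtype=float)
    t = np.asarray(y_true, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return p, t


def cross_entropy(y_pred, y_true, clip: float = 1e-7,
                  reduction: str = "sum") -> float:
    """Binary cross-entropy between vessel probabilities and 0/1 labels."""
    p, t = _check(y_pred, y_true)
    p = np.clip(p, clip, 1.0 - clip)
    ce = -(t * np.log(p) + (1.0 - t) * np.log(1.0 - p))
    return float(ce.sum() if reduction == "sum" else ce.mean())


def cross_entropy_grad(y_pred, y_true, clip: float = 1e-7,
                       reduction: str = "sum") -> np.ndarray:
    """d L_CE / d y_pred; zero where the clip is active."""
    p, t = _check(y_pred, y_true)
    pc = np.clip(p, clip, 1.0 - clip)
    g = (pc - t) / (pc * (1.0 - pc))
    g = np.where((p > clip) & (p < 1.0 - clip), g, 0.0)
    return g if reduction == "sum" else g / p.size


def dice_loss(y_pred, y_true, smooth: float = 1.0) -> float:
    """One minus the smoothed Dice overlap of predictions and labels."""
    p, t = _check(y_pred, y_true)
    num = 2.0 * (t * p).sum() + smooth
    den = t.sum() + p.sum() + smooth
    return float(1.0 - num / den)


def dice_loss_grad(y_pred, y_true, smooth: float = 1.0) -> np.ndarray:
    """d L_Dice / d y_pred (quotient rule on the smoothed overlap)."""
    p, t = _check(y_pred, y_true)
    num = 2.0 * (t * p).sum() + smooth
    den = t.sum() + p.sum() + smooth
    return -(2.0 * t * den - num) / (den * den)


def combined_loss(y_pred, y_true, cfg: LossConfig | None = None) -> float:
    """L_CE + L_Dice with the config's smoothing, clipping and reduction."""
    cfg = cfg or LossConfig()
    return (cross_entropy(y_pred, y_true, cfg.clip, cfg.reduction)
            + dice_loss(y_pred, y_true, cfg.smooth))


def combined_loss_grad(y_pred, y_true, cfg: LossConfig | None = None) -> np.ndarray:
    cfg = cfg or LossConfig()
    return (cross_entropy_grad(y_pred, y_true, cfg.clip, cfg.reduction)
            + dice_loss_grad(y_pred, y_true, cfg.smooth))


def segmentation_loss(probs: np.ndarray, labels: np.ndarray,
                      cfg: LossConfig | None = None) -> tuple[float, np.ndarray]:
    """Loss and gradient w.r.t. the softmax output of a segmentation model.

    probs: (N, H, W, 2) per-pixel class probabilities (channel 1 = vessel);
    labels: (N, H, W) binary masks. The Dice term uses the vessel channel
    only; because the two softmax channels are complementary, two-class
    cross-entropy equals binary CE on the vessel channel, and the whole
    gradient can be carried on that channel through the softmax layer.
    """
    cfg = cfg or LossConfig()
    p1 = probs[..., 1].astype(float)
    t = np.asarray(labels, dtype=float)
    if p1.shape != t.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs labels {t.shape}")
    loss = combined_loss(p1, t, cfg)
    dfull = np.zeros_like(probs)
    dfull[..., 1] = combined_loss_grad(p1, t, cfg)
    return loss, dfull


def segmentation_loss_logits(probs: np.ndarray, labels: np.ndarray,
                             cfg: LossConfig | None = None) -> tuple[float, np.ndarray]:
    """Loss and gradient w.r.t. the *pre-softmax logits* (fused form).

    Identical loss value to :func:`segmentation_loss`, but the gradient
    is taken through the softmax analytically: the cross-entropy part
    becomes the bounded p - y, which stays informative even where the
    float32 softmax saturates to exactly 0 or 1 (where a probability-
    space gradient would vanish against the clip). This is what the
    trainer uses.
    """
    cfg = cfg or LossConfig()
    p1 = probs[..., 1].astype(float)
    t = np.asarray(labels, dtype=float)
    if p1.shape != t.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs labels {t.shape}")
    loss = combined_loss(p1, t, cfg)
    ce_scale = 1.0 if cfg.reduction == "sum" else 1.0 / p1.size
    # softmax-CE: dL/dlogit_1 = p1 - y (channel 0 is the negation)
    d1 = (p1 - t) * ce_scale
    # Dice: bounded probability gradient pushed through the softmax jacobian
    d1 = d1 + dice_loss_grad(p1, t, cfg.smooth) * p1 * (1.0 - p1)
    dlogits = np.empty_like(probs)
    dlogits[..., 1] = d1
    dlogits[..., 0] = -d1
    return loss, dlogits
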