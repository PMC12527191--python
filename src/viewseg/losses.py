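"""Training objectives for joint tumor segmentation and detection.

All functions are pure NumPy and operate on plain arrays.  Overlap losses
(Dice, Tversky, IoU) accept either a single ``(H, W)`` map pair or a batch
``(B, H, W)``; batches are reduced by averaging the per-image losses, so a
tumor-free image whose prediction is also empty contributes a loss of zero
instead of diluting the foreground sums of the rest of the batch.

The composite objective is

    L_total = (1 - lambda) * L_seg + lambda * L_cls
    L_seg   = w * L_Dice + (1 - w) * L_Tversky(alpha, beta)
    L_cls   = gamma * L_BCE + (1 - gamma) * L_IoU

where ``L_BCE`` is the numerically stable binary cross-entropy with logits
and every overlap term is smoothed by a small ``eps`` so that an empty
prediction compared against an empty ground truth scores a perfect 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossConfig",
    "softmax",
    "class_weights",
    "weighted_cross_entropy",
    "dice_loss",
    "tversky_loss",
    "segmentation_loss",
    "bce_logit_loss",
    "iou_loss",
    "classification_loss",
    "total_loss",
]


@dataclass(frozen=True)
class LossConfig:
    """Scalar weights of the composite objective.

    Parameters
    ----------
    w : float
        Dice-vs-Tversky mixing weight in [0, 1].
    alpha : float
        Tversky false-negative weight (>= 0).  ``alpha > beta`` emphasises
        recall, which favours small tumors.
    beta : float
        Tversky false-positive weight (>= 0).
    gamma : float
        BCE-vs-IoU mixing weight in [0, 1].
    lam : float
        Classification-vs-segmentation weight in [0, 1].
    eps : float
        Smoothing constant (> 0) added to overlap numerators and
        denominators; keeps empty-vs-empty comparisons at a perfect score.
    """

    w: float = 0.4
    alpha: float = 0.7
    beta: float = 0.3
    gamma: float = 0.7
    lam: float = 0.2
    eps: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("w", "gamma", "lam"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


# ---------------------------------------------------------------------------
# classifier objectives


def softmax(logits: np.ndarray) -> np.ndarray:
    """Shift-invariant softmax over the last axis.

    Raises ``ValueError`` on non-finite input.
    """
    z = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax requires finite logits")
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def class_weights(counts) -> np.ndarray:
    """Inverse-frequency class weights: total count / per-class count."""
    c = np.asarray(counts, dtype=np.float64)
    if c.ndim != 1 or c.size == 0:
        raise ValueError("counts must be a non-empty 1-D sequence")
    if np.any(c <= 0):
        raise ValueError("all class counts must be positive")
    return c.sum() / c


def weighted_cross_entropy(logits, true_class, weights) -> float:
    """Weighted cross-entropy with one-hot ground truth.

    ``logits`` may be a single ``(C,)`` vector with an integer
    ``true_class``, or a ``(B, C)`` batch with a length-``B`` index array;
    batches are reduced by the mean.
    """
    z = np.asarray(logits, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    single = z.ndim == 1
    zb = z[None, :] if single else z
    tc = np.atleast_1d(np.asarray(true_class, dtype=np.int64))
    C = zb.shape[1]
    if w.shape != (C,):
        raise ValueError(f"weights must have length {C}")
    if np.any(tc < 0) or np.any(tc >= C):
        raise ValueError(f"true_class must lie in [0, {C})")
    if tc.shape[0] != zb.shape[0]:
        raise ValueError("true_class length must match the batch size")
    # stable log-softmax
    shifted = zb - zb.max(axis=1, keepdims=True)
    log_s = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    per = -w[tc] * log_s[np.arange(zb.shape[0]), tc]
    return float(per.mean())


# ---------------------------------------------------------------------------
# overlap losses


def _as_batch(a: np.ndarray) -> np.ndarray:
    """Flatten to (B, n_pixels); 1-D and 2-D inputs are a single image."""
    if a.ndim <= 2:
        return a.reshape(1, -1)
    return a.reshape(a.shape[0], -1)


def dice_loss(pred, target, eps: float = 1e-6) -> float:
    """Soft Dice loss ``1 - (2*sum(o*g) + eps) / (sum(o) + sum(g) + eps)``."""
    o = np.asarray(pred, dtype=np.float64)
    g = np.asarray(target, dtype=np.float64)
    if o.shape != g.shape:
        raise ValueError(f"dice_loss: shape mismatch {o.shape} vs {g.shape}")
    if o.size == 0:
        raise ValueError("dice_loss: empty input")
    if o.min() < -1e-12 or o.max() > 1 + 1e-12:
        raise ValueError("dice_loss: predictions must lie in [0, 1]")
    ob, gb = _as_batch(o), _as_batch(g)
    inter = (ob * gb).sum(axis=1)
    denom = ob.sum(axis=1) + gb.sum(axis=1)
    per = 1.0 - (2.0 * inter + eps) / (denom + eps)
    return float(per.mean())


def tversky_loss(pred, target, alpha: float = 0.7, beta: float = 0.3,
                 eps: float = 1e-6) -> float:
    """Tversky loss with false-negative weight ``alpha`` and
    false-positive weight ``beta``; ``alpha = beta = 0.5`` recovers Dice."""
    if alpha < 0 or beta < 0:
        raise ValueError("tversky_loss: alpha and beta must be non-negative")
    o = np.asarray(pred, dtype=np.float64)
    g = np.asarray(target, dtype=np.float64)
    if o.shape != g.shape:
        raise ValueError(f"tversky_loss: shape mismatch {o.shape} vs {g.shape}")
    if o.size == 0:
        raise ValueError("tversky_loss: empty input")
    if o.min() < -1e-12 or o.max() > 1 + 1e-12:
        raise ValueError("tversky_loss: predictions must lie in [0, 1]")
    ob, gb = _as_batch(o), _as_batch(g)
    tp = (ob * gb).sum(axis=1)
    fn = ((1.0 - ob) * gb).sum(axis=1)
    fp = (ob * (1.0 - gb)).sum(axis=1)
    per = 1.0 - (tp + eps) / (tp + alpha * fn + beta * fp + eps)
    return float(per.mean())


def segmentation_loss(pred, target, cfg: LossConfig) -> float:
    """Weighted sum ``w * Dice + (1 - w) * Tversky(alpha, beta)``."""
    ld = dice_loss(pred, target, eps=cfg.eps)
    lt = tversky_loss(pred, target, alpha=cfg.alpha, beta=cfg.beta, eps=cfg.eps)
    return cfg.w * ld + (1.0 - cfg.w) * lt


def bce_logit_loss(logits, target) -> float:
    """Binary cross-entropy with logits, averaged over every element.

    Computed in the numerically stable form
    ``log(1 + exp(-p)) + p * (1 - t)`` via ``logaddexp``.
    """
    p = np.asarray(logits, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"bce_logit_loss: shape mismatch {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("bce_logit_loss: empty input")
    val = np.logaddexp(0.0, -p) + p * (1.0 - t)
    return float(val.mean())


def iou_loss(pred, target, eps: float = 1e-6) -> float:
    """Soft Jaccard loss ``1 - (inter + eps) / (union + eps)``."""
    o = np.asarray(pred, dtype=np.float64)
    g = np.asarray(target, dtype=np.float64)
    if o.shape != g.shape:
        raise ValueError(f"iou_loss: shape mismatch {o.shape} vs {g.shape}")
    if o.size == 0:
        raise ValueError("iou_loss: empty input")
    if o.min() < -1e-12 or o.max() > 1 + 1e-12:
        raise ValueError("iou_loss: predictions must lie in [0, 1]")
    ob, gb = _as_batch(o), _as_batch(g)
    inter = (ob * gb).sum(axis=1)
    union = ob.sum(axis=1) + gb.sum(axis=1) - inter
    per = 1.0 - (inter + eps) / (union + eps)
    return float(per.mean())


def classification_loss(logits, pred_prob, target, cfg: LossConfig) -> float:
    """``gamma * BCE(logits, target) + (1 - gamma) * IoU(pred_prob, target)``.

    In the default (mask-rule header) configuration both terms are computed
    on the segmentation maps against the ground-truth mask, so the element
    count is batch x height x width.
    """
    lb = bce_logit_loss(logits, target)
    li = iou_loss(pred_prob, target, eps=cfg.eps)
    return cfg.gamma * lb + (1.0 - cfg.gamma) * li


def total_loss(seg_loss_value: float, cls_loss_value: float,
               cfg: LossConfig) -> float:
    """``(1 - lambda) * L_seg + lambda * L_cls``."""
    lam = cfg.lam
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return (1.0 - lam) * float(seg_loss_value) + lam * float(cls_loss_value)
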