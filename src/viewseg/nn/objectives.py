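"""Loss values and analytic gradients used by the training loops.

The public loss functions in :mod:`viewseg.losses` are pure scalar
evaluations; the training code additionally needs the gradients of the
composite objective with respect to the network outputs.  Those gradients
are derived in closed form here (quotient rule for the overlap terms,
``sigmoid(p) - t`` for the BCE-with-logits terms) and are verified against
finite differences in the test suite.

All overlap terms are computed per image and averaged over the batch,
matching the reduction convention of :mod:`viewseg.losses`.
"""

from __future__ import annotations

import numpy as np

from viewseg.losses import LossConfig

__all__ = ["sigmoid", "weighted_ce_with_grad", "segclass_objective"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def weighted_ce_with_grad(logits: np.ndarray, true_class: np.ndarray,
                          weights: np.ndarray):
    """Weighted cross-entropy (batch mean) and its gradient w.r.t. logits."""
    z = np.asarray(logits, dtype=np.float64)
    tc = np.asarray(true_class, dtype=np.int64)
    B, C = z.shape
    shifted = z - z.max(axis=1, keepdims=True)
    log_s = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    s = np.exp(log_s)
    wb = np.asarray(weights, dtype=np.float64)[tc]
    loss = float((-wb * log_s[np.arange(B), tc]).mean())
    onehot = np.zeros_like(z)
    onehot[np.arange(B), tc] = 1.0
    dlogits = wb[:, None] * (s - onehot) / B
    return loss, dlogits


# ---------------------------------------------------------------------------
# per-image overlap terms with gradients w.r.t. the probability map


def _dice_terms(o, g, eps):
    inter = (o * g).sum(axis=(1, 2))
    denom = o.sum(axis=(1, 2)) + g.sum(axis=(1, 2))
    num = 2.0 * inter + eps
    den = denom + eps
    loss = 1.0 - num / den
    dL_do = -(2.0 * g * den[:, None, None] - num[:, None, None]) / (
        den ** 2)[:, None, None]
    return loss, dL_do


def _tversky_terms(o, g, alpha, beta, eps):
    tp = (o * g).sum(axis=(1, 2))
    fn = ((1.0 - o) * g).sum(axis=(1, 2))
    fp = (o * (1.0 - g)).sum(axis=(1, 2))
    num = tp + eps
    den = tp + alpha * fn + beta * fp + eps
    loss = 1.0 - num / den
    dden_do = g * (1.0 - alpha) + beta * (1.0 - g)
    dL_do = -(g * den[:, None, None] - num[:, None, None] * dden_do) / (
        den ** 2)[:, None, None]
    return loss, dL_do


def _iou_terms(o, g, eps):
    inter = (o * g).sum(axis=(1, 2))
    union = o.sum(axis=(1, 2)) + g.sum(axis=(1, 2)) - inter
    num = inter + eps
    den = union + eps
    loss = 1.0 - num / den
    dL_do = -(g * den[:, None, None] - num[:, None, None] * (1.0 - g)) / (
        den ** 2)[:, None, None]
    return loss, dL_do


def _batch_iou_vec(q, y, eps):
    """Soft Jaccard over a batch of scalar label probabilities."""
    inter = (q * y).sum()
    union = q.sum() + y.sum() - inter
    num, den = inter + eps, union + eps
    loss = 1.0 - num / den
    dL_dq = -(y * den - num * (1.0 - y)) / den ** 2
    return loss, dL_dq


def segclass_objective(seg_logits: np.ndarray, head_logits,
                       masks: np.ndarray, labels: np.ndarray,
                       cfg: LossConfig, header_mode: str = "mask-rule"):
    """Composite objective and gradients for one batch.

    Parameters
    ----------
    seg_logits : (B, H, W) array
        Raw decoder output.
    head_logits : (B,) array or None
        Classification-head logits (required for ``header_mode='learned'``).
    masks : (B, H, W) binary array
        Ground-truth masks.
    labels : (B,) binary array
        Tumor-presence labels.
    cfg : LossConfig
    header_mode : {'mask-rule', 'learned'}
        With the parameter-free mask-rule head the classification term is
        evaluated on the segmentation maps against the ground-truth mask
        (element count batch x height x width).  With a learned head it is
        evaluated on the head logits against the image-level labels.

    Returns
    -------
    (total, components, d_seg_logits, d_head_logits)
        ``components`` maps ``{'seg','cls','dice','tversky','bce','iou'}``
        to floats; gradients are already scaled for the batch mean.
    """
    z = np.asarray(seg_logits, dtype=np.float64)
    g = np.asarray(masks, dtype=np.float64)
    B = z.shape[0]
    o = sigmoid(z)
    eps = cfg.eps

    dice, d_dice = _dice_terms(o, g, eps)
    tv, d_tv = _tversky_terms(o, g, cfg.alpha, cfg.beta, eps)
    seg_per = cfg.w * dice + (1.0 - cfg.w) * tv
    dseg_do = (cfg.w * d_dice + (1.0 - cfg.w) * d_tv) / B
    seg = float(seg_per.mean())

    d_head = None
    if header_mode == "mask-rule":
        n_el = z.size
        bce = float((np.logaddexp(0.0, -z) + z * (1.0 - g)).mean())
        dbce_dz = (o - g) / n_el
        iou, d_iou = _iou_terms(o, g, eps)
        iou_val = float(iou.mean())
        dcls_do = (1.0 - cfg.gamma) * d_iou / B
        dcls_dz_direct = cfg.gamma * dbce_dz
        cls = cfg.gamma * bce + (1.0 - cfg.gamma) * iou_val
    elif header_mode == "learned":
        if head_logits is None:
            raise ValueError("learned header mode requires head logits")
        h = np.asarray(head_logits, dtype=np.float64)
        y = np.asarray(labels, dtype=np.float64)
        q = sigmoid(h)
        bce = float((np.logaddexp(0.0, -h) + h * (1.0 - y)).mean())
        dbce_dh = (q - y) / B
        iou_val, diou_dq = _batch_iou_vec(q, y, eps)
        cls = cfg.gamma * bce + (1.0 - cfg.gamma) * iou_val
        d_head = cfg.lam * (cfg.gamma * dbce_dh
                            + (1.0 - cfg.gamma) * diou_dq * q * (1.0 - q))
        dcls_do = 0.0
        dcls_dz_direct = 0.0
    else:
        raise ValueError(f"unknown header mode: {header_mode!r}")

    total = (1.0 - cfg.lam) * seg + cfg.lam * cls
    do_total = (1.0 - cfg.lam) * dseg_do
    if header_mode == "mask-rule":
        do_total = do_total + cfg.lam * dcls_do
    dz = do_total * o * (1.0 - o)
    if header_mode == "mask-rule":
        dz = dz + cfg.lam * dcls_dz_direct

    components = {
        "seg": seg, "cls": cls, "dice": float(dice.mean()),
        "tversky": float(tv.mean()), "bce": bce, "iou": float(iou_val),
        "total": total,
    }
    return total, components, dz, d_head
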