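"""Training loops, evaluation and parameter sweeps.

Both trainers use AdamW.  The view classifier minimises inverse-frequency
weighted cross-entropy, with class weights computed from the training
split.  The segmentation-classification trainer minimises the composite
objective ``(1 - lambda) * L_seg + lambda * L_cls`` and retains the
checkpoint with the best validation Dice.

Default hyper-parameters follow the full-scale study setup (classifier:
30 epochs, batch 16, lr 1e-5, weight decay 0.05; segmentation: 20 epochs,
batch 3, lr 1e-3); the desk-scale phantom experiments override them
explicitly.
"""

from __future__ import annotations

import copy
import csv
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from viewseg.losses import LossConfig, class_weights
from viewseg.metrics import MetricsRecord, binarize, classification_report, \
    dice_score, iou_score
from viewseg.models import ModelBundle, SegClassModel, ViewClassifierModel, \
    ViewLabel, build_segclass_model, classify_view, detect
from viewseg.nn.objectives import segclass_objective, sigmoid, \
    weighted_ce_with_grad
from viewseg.nn.optim import AdamW
from viewseg.preprocess import AugmentConfig, classifier_augment, normalize, \
    paired_augment, resize

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "classifier_defaults",
    "segmentation_defaults",
    "train_view_classifier",
    "train_segclass",
    "predict_probmaps",
    "evaluate",
    "sweep",
]


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 3
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    freeze_encoder: bool = False
    augment: AugmentConfig | None = None
    strict_view: bool = True
    class_weighting: bool = True  # inverse-frequency weights for the classifier

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def classifier_defaults(**overrides) -> TrainConfig:
    """Full-scale view-classifier schedule: 30 epochs, batch 16, lr 1e-5,
    weight decay 0.05."""
    base = dict(epochs=30, batch_size=16, learning_rate=1e-5,
                weight_decay=0.05)
    base.update(overrides)
    return TrainConfig(**base)


def segmentation_defaults(**overrides) -> TrainConfig:
    """Full-scale segmentation schedule: 20 epochs, batch 3, lr 1e-3."""
    base = dict(epochs=20, batch_size=3, learning_rate=1e-3,
                weight_decay=0.0)
    base.update(overrides)
    return TrainConfig(**base)


@dataclass
class TrainHistory:
    rows: list[dict] = field(default_factory=list)
    steps: list[dict] = field(default_factory=list)
    best_epoch: int = -1

    def __len__(self) -> int:
        return len(self.rows)

    def to_csv(self, path) -> None:
        if not self.rows:
            return
        with open(path, "w", newline="") as fh:
            wr = csv.DictWriter(fh, fieldnames=list(self.rows[0]))
            wr.writeheader()
            wr.writerows(self.rows)


# ---------------------------------------------------------------------------
# batch plumbing


def _to_input(sample, image_size: int, mean: float, std: float,
              rng=None, augment: AugmentConfig | None = None):
    img = sample.image
    if img.shape[0] != image_size:
        img = resize(img, target_size=image_size)
    if rng is not None and augment is not None:
        img = classifier_augment(img, rng, augment)
    return normalize(img, mean, std)


def _input_stats(augment: AugmentConfig | None):
    if augment is None:
        return 0.5, 0.5
    return augment.mean, augment.std


def _iter_batches(n: int, batch_size: int, rng=None):
    order = np.arange(n) if rng is None else rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


# ---------------------------------------------------------------------------
# view classifier


def train_view_classifier(model: ViewClassifierModel, train_data, val_data,
                          cfg: TrainConfig):
    """Optimise weighted cross-entropy; returns (model, history)."""
    if not train_data:
        raise ValueError("empty training data")
    rng = np.random.default_rng(cfg.seed)
    counts = np.bincount([int(s.view) for s in train_data], minlength=3)
    if (counts == 0).any():
        # absent classes get weight 0 contribution anyway; avoid div-by-zero
        counts = np.maximum(counts, 1)
    weights = class_weights(counts) if cfg.class_weighting else np.ones(3)
    mean, std = _input_stats(cfg.augment)
    aug = cfg.augment if (cfg.augment is not None
                          and "classifier" in cfg.augment.enabled_for) else None
    size = model.cfg.image_size
    opt = AdamW(model.net.params(), lr=cfg.learning_rate,
                weight_decay=cfg.weight_decay)
    history = TrainHistory()
    for epoch in range(cfg.epochs):
        losses = []
        for idx in _iter_batches(len(train_data), cfg.batch_size, rng):
            xs = np.stack([
                np.repeat(_to_input(train_data[i], size, mean, std,
                                    rng=rng, augment=aug)[..., None], 3, axis=2)
                for i in idx])
            ys = np.array([int(train_data[i].view) for i in idx])
            logits = model.net.forward(xs, train=True)
            loss, dlog = weighted_ce_with_grad(logits, ys, weights)
            opt.zero_grad()
            model.net.backward(dlog)
            opt.step()
            losses.append(loss)
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_data:
            vl, va = _classifier_eval(model, val_data, weights, mean, std)
            row.update(val_loss=vl, val_acc=va)
        history.rows.append(row)
    history.best_epoch = len(history.rows) - 1
    return model, history


def _classifier_eval(model, data, weights, mean, std, batch: int = 32):
    size = model.cfg.image_size
    losses, correct = [], 0
    for idx in _iter_batches(len(data), batch):
        xs = np.stack([np.repeat(_to_input(data[i], size, mean, std)[..., None],
                                 3, axis=2) for i in idx])
        ys = np.array([int(data[i].view) for i in idx])
        logits = model.net.forward(xs, train=False)
        loss, _ = weighted_ce_with_grad(logits, ys, weights)
        losses.append(loss * len(idx))
        correct += int((logits.argmax(axis=1) == ys).sum())
    return float(np.sum(losses) / len(data)), correct / len(data)


# ---------------------------------------------------------------------------
# segmentation-classification


def train_segclass(model: SegClassModel, train_data, val_data,
                   cfg: TrainConfig):
    """Optimise the composite objective; keeps the best-validation-Dice
    checkpoint.  Returns (model, history)."""
    if not train_data:
        raise ValueError("empty training data")
    if cfg.strict_view:
        views = {int(s.view) for s in list(train_data) + list(val_data or [])}
        if len(views) > 1:
            raise ValueError(
                f"mixed views {sorted(views)} in single-view training; "
                "disable strict_view to override")
    rng = np.random.default_rng(cfg.seed)
    mean, std = _input_stats(cfg.augment)
    aug = cfg.augment if (cfg.augment is not None and
                          "segmentation" in cfg.augment.enabled_for) else None
    size = model.cfg.image_size
    header_mode = model.cfg.header_mode
    params = (model.net.decoder_params() if cfg.freeze_encoder
              else model.net.params())
    opt = AdamW(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    history = TrainHistory()
    best_dice, best_state = -1.0, None
    for epoch in range(cfg.epochs):
        tot = []
        for idx in _iter_batches(len(train_data), cfg.batch_size, rng):
            xs, ms = [], []
            for i in idx:
                s = train_data[i]
                img, msk = s.image, s.mask
                if img.shape[0] != size:
                    img, msk = resize(img, msk, target_size=size)
                if aug is not None:
                    img, msk = paired_augment(img, msk, rng, aug)
                img = normalize(img, mean, std)
                xs.append(np.repeat(img[..., None], 3, axis=2))
                ms.append(msk)
            xs = np.stack(xs)
            masks = np.stack(ms).astype(np.float64)
            labels = np.array([int(train_data[i].tumor_label) for i in idx])
            seg_logits, head_logits = model.net.forward(xs, train=True)
            total, comps, dz, dh = segclass_objective(
                seg_logits, head_logits, masks, labels, cfg.loss, header_mode)
            opt.zero_grad()
            model.net.backward(dz, dh)
            opt.step()
            tot.append(total)
            history.steps.append(comps)
        row = {"epoch": epoch, "train_loss": float(np.mean(tot))}
        if val_data:
            vm = _segclass_eval(model, val_data, cfg, header_mode)
            row.update(vm)
            if vm["val_dice"] > best_dice:
                best_dice = vm["val_dice"]
                best_state = copy.deepcopy(model.net.state_dict())
                history.best_epoch = epoch
        history.rows.append(row)
    if best_state is not None:
        model.net.load_state_dict(best_state)
    elif history.best_epoch < 0:
        history.best_epoch = len(history.rows) - 1
    return model, history


def _segclass_eval(model, data, cfg, header_mode, tau: float | None = None):
    tau = tau if tau is not None else model.cfg.threshold
    probs, heads = predict_probmaps(model, data)
    dices, pred_labels = [], []
    size = model.cfg.image_size
    for k, s in enumerate(data):
        msk = s.mask
        if msk.shape[0] != size:
            _, msk = resize(s.image, msk, target_size=size)
        pred = binarize(probs[k], tau)
        dices.append(dice_score(pred, msk))
        pred_labels.append(detect(
            probs[k], model.cfg.header_mode,
            threshold=model.cfg.threshold,
            min_area_frac=model.cfg.min_area_frac,
            head_logit=heads[k] if heads is not None else None))
    true_labels = [int(s.tumor_label) for s in data]
    rep = classification_report(pred_labels, true_labels)
    return {"val_loss": float("nan"), "val_dice": float(np.mean(dices)),
            "val_f1": rep.f1}


def predict_probmaps(model: SegClassModel, samples, batch: int = 16):
    """Probability maps (and head logits, if present) for a sample list."""
    mean, std = 0.5, 0.5
    size = model.cfg.image_size
    probs, heads = [], []
    for idx in _iter_batches(len(samples), batch):
        xs = np.stack([np.repeat(
            _to_input(samples[i], size, mean, std)[..., None], 3, axis=2)
            for i in idx])
        seg_logits, head_logits = model.net.forward(xs, train=False)
        probs.extend(sigmoid(seg_logits).astype(np.float32))
        if head_logits is not None:
            heads.extend(head_logits.tolist())
    return probs, (heads if heads else None)


# ---------------------------------------------------------------------------
# evaluation


def evaluate(model_or_bundle, samples, tau: float = 0.65):
    """Per-image IoU/Dice plus image-level detection metrics.

    Accepts a single :class:`SegClassModel` or a routed
    :class:`ModelBundle`.  Returns a dict with per-image ``rows``, an
    ``overall`` :class:`MetricsRecord` (mean per-image IoU/Dice; detection
    precision/recall/F1/accuracy), a ``per_view`` breakdown and the
    pixel-level F1 under ``overall.extra['pixel_f1']``.
    """
    if not samples:
        raise ValueError("empty evaluation data")
    rows = []
    pix_tp = pix_fp = pix_fn = 0
    for s in samples:
        if isinstance(model_or_bundle, ModelBundle):
            clf = model_or_bundle.view_classifier
            view = classify_view(clf, _to_input(s, clf.cfg.image_size,
                                                0.5, 0.5))
            model = model_or_bundle.per_view_models[view]
        else:
            model = model_or_bundle
            view = s.view
        probs, heads = predict_probmaps(model, [s])
        prob = probs[0]
        size = model.cfg.image_size
        msk = s.mask
        if msk.shape[0] != size:
            _, msk = resize(s.image, msk, target_size=size)
        pred = binarize(prob, tau)
        label = detect(prob, model.cfg.header_mode,
                       threshold=model.cfg.threshold,
                       min_area_frac=model.cfg.min_area_frac,
                       head_logit=heads[0] if heads is not None else None)
        pix_tp += int((pred * msk).sum())
        pix_fp += int((pred * (1 - msk)).sum())
        pix_fn += int(((1 - pred) * msk).sum())
        rows.append({
            "id": s.sample_id, "view": ViewLabel(view).name.lower(),
            "iou": iou_score(pred, msk), "dice": dice_score(pred, msk),
            "pred_label": label, "true_label": int(s.tumor_label),
        })
    out = {"rows": rows, "overall": _aggregate(rows), "per_view": {}}
    for view in ViewLabel:
        vrows = [r for r in rows if r["view"] == view.name.lower()]
        if vrows:
            out["per_view"][view] = _aggregate(vrows)
    denom_p = 2 * pix_tp + pix_fp + pix_fn
    out["overall"].extra["pixel_f1"] = (
        2 * pix_tp / denom_p if denom_p else 1.0)
    return out


def _aggregate(rows) -> MetricsRecord:
    rep = classification_report([r["pred_label"] for r in rows],
                                [r["true_label"] for r in rows])
    rec = MetricsRecord(
        iou=float(np.mean([r["iou"] for r in rows])),
        dice=float(np.mean([r["dice"] for r in rows])),
        f1=rep.f1, precision=rep.precision, recall=rep.recall,
        accuracy=rep.accuracy)
    rec.extra["n"] = len(rows)
    return rec


# ---------------------------------------------------------------------------
# parameter sweeps


def sweep(parameter: str, values, base_cfg: TrainConfig, data, seeds,
          model_cfg=None, tau: float = 0.65) -> pd.DataFrame:
    """Sensitivity harness over ``lambda`` (retrains per value) or
    ``threshold`` (trains once per seed, re-thresholds the predictions).

    ``data`` is a ``(train, val, test)`` triple of sample lists.  Returns a
    tidy DataFrame with one row per (value, seed).
    """
    from viewseg.models import SegClassConfig

    if parameter not in ("lambda", "threshold"):
        raise ValueError("parameter must be 'lambda' or 'threshold'")
    values = list(values)
    if not values:
        raise ValueError("empty sweep value list")
    train_data, val_data, test_data = data
    model_cfg = model_cfg or SegClassConfig()
    records = []
    if parameter == "lambda":
        for lam in values:
            for seed in seeds:
                cfg = replace(base_cfg, seed=seed,
                              loss=replace(base_cfg.loss, lam=float(lam)))
                model = build_segclass_model(model_cfg, seed=seed)
                model, _ = train_segclass(model, train_data, val_data, cfg)
                res = evaluate(model, test_data, tau=tau)
                records.append(_sweep_row("lambda", lam, seed, res))
    else:
        for seed in seeds:
            cfg = replace(base_cfg, seed=seed)
            model = build_segclass_model(model_cfg, seed=seed)
            model, _ = train_segclass(model, train_data, val_data, cfg)
            for t in values:
                res = evaluate(model, test_data, tau=float(t))
                records.append(_sweep_row("threshold", t, seed, res))
    return pd.DataFrame.from_records(records)


def _sweep_row(param, value, seed, res) -> dict:
    o = res["overall"]
    return {"parameter": param, "value": float(value), "seed": seed,
            "iou": o.iou, "dice": o.dice, "f1": o.f1,
            "precision": o.precision, "recall": o.recall,
            "accuracy": o.accuracy}
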