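"""End-to-end routed inference: preprocess -> classify view -> route to the
view-specific model -> segment -> decide tumor presence.

Every input image receives exactly one (mask, label) pair; routing invokes
exactly one per-view model per image, or a forced view when requested.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from viewseg.metrics import binarize, classification_report, dice_score, \
    iou_score
from viewseg.models import (
    ModelBundle,
    SegClassModel,
    ViewClassifierModel,
    ViewLabel,
    classify_view,
    detect,
)
from viewseg.nn.objectives import sigmoid
from viewseg.preprocess import normalize, resize

__all__ = [
    "DiagnosisResult",
    "infer_image",
    "run_directory",
    "save_bundle",
    "load_bundle",
]

logger = logging.getLogger("viewseg")

BUNDLE_VERSION = 1
_BUNDLE_FILES = {
    "classifier": "classifier.npz",
    ViewLabel.AXIAL: "axial.npz",
    ViewLabel.CORONAL: "coronal.npz",
    ViewLabel.SAGITTAL: "sagittal.npz",
}


@dataclass
class DiagnosisResult:
    image_id: str
    view: ViewLabel
    prob_map: np.ndarray     # (H, W) float32 in [0, 1]
    mask: np.ndarray         # (H, W) uint8 in {0, 1}
    tumor_label: int


def infer_image(bundle: ModelBundle, image, image_id: str = "",
                force_view: ViewLabel | None = None,
                tau: float | None = None) -> DiagnosisResult:
    """Route one image through the bundle and return its diagnosis."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 3:  # collapse RGB to gray; channels are replicated anyway
        img = img.mean(axis=2)
    size = bundle.view_classifier.cfg.image_size
    if img.shape[0] != size or img.shape[1] != size:
        img = resize(img, target_size=size)
    norm = normalize(img)
    if force_view is not None:
        view = ViewLabel(force_view)
    else:
        view = classify_view(bundle.view_classifier, norm)
    model = bundle.per_view_models[view]
    seg_logits, head_logits = model.forward([norm])
    prob = sigmoid(seg_logits[0]).astype(np.float32)
    tau = tau if tau is not None else model.cfg.threshold
    mask = binarize(prob, tau)
    label = detect(prob, model.cfg.header_mode,
                   threshold=model.cfg.threshold,
                   min_area_frac=model.cfg.min_area_frac,
                   head_logit=head_logits[0] if head_logits is not None
                   else None)
    return DiagnosisResult(image_id=image_id, view=view, prob_map=prob,
                           mask=mask, tumor_label=label)


def infer_batch(bundle: ModelBundle, images, ids=None,
                force_view: ViewLabel | None = None,
                tau: float | None = None) -> list[DiagnosisResult]:
    """Order-preserving batch inference: n images in, n results out."""
    ids = ids or [str(i) for i in range(len(images))]
    return [infer_image(bundle, im, image_id=i, force_view=force_view,
                        tau=tau) for im, i in zip(images, ids)]


def _find_images(input_dir: Path) -> list[tuple[str, Path, Path | None]]:
    """Collect (id, image path, optional mask path) from a flat directory of
    PNG/JPEG files or the per-view dataset layout."""
    entries = []
    img_dirs = sorted(input_dir.glob("*/images")) or [input_dir]
    for d in img_dirs:
        for p in sorted(d.iterdir()):
            if p.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            mask_path = d.parent / "masks" / p.name if d.name == "images" \
                else None
            entries.append((p.stem, p,
                            mask_path if mask_path and mask_path.exists()
                            else None))
    return entries


def run_directory(bundle: ModelBundle, input_dir, output_dir,
                  force_view: ViewLabel | None = None,
                  tau: float | None = None) -> dict:
    """Run the pipeline over every image in a directory.

    Writes per-image mask PNGs and a manifest CSV
    (``id,predicted_view,tumor_label,mask_path``); when ground-truth masks
    are present alongside the images a metrics report JSON is added.
    Unreadable images are logged and skipped; their count is reported in
    the returned summary.
    """
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    entries = _find_images(input_dir)
    if not entries:
        raise ValueError(f"no images found under {input_dir}")
    (output_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows, results, errors = [], [], 0
    truth = []
    for image_id, img_path, mask_path in entries:
        try:
            img = np.asarray(Image.open(img_path).convert("L"),
                             dtype=np.float32) / 255.0
        except Exception as exc:  # unreadable file: skip but keep going
            logger.warning("skipping unreadable image %s: %s", img_path, exc)
            errors += 1
            continue
        res = infer_image(bundle, img, image_id=image_id,
                          force_view=force_view, tau=tau)
        out_path = output_dir / "masks" / f"{image_id}.png"
        Image.fromarray((res.mask * 255).astype(np.uint8)).save(out_path)
        rows.append({"id": image_id,
                     "predicted_view": res.view.name.lower(),
                     "tumor_label": res.tumor_label,
                     "mask_path": str(out_path.relative_to(output_dir))})
        results.append(res)
        if mask_path is not None:
            gt = (np.asarray(Image.open(mask_path).convert("L")) > 127)
            truth.append(gt.astype(np.uint8))
        else:
            truth.append(None)
    manifest = output_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        wr = csv.DictWriter(fh, fieldnames=["id", "predicted_view",
                                            "tumor_label", "mask_path"])
        wr.writeheader()
        wr.writerows(rows)
    summary = {"n_inputs": len(entries), "n_processed": len(rows),
               "n_errors": errors, "manifest": str(manifest)}
    scored = [(r, t) for r, t in zip(results, truth) if t is not None]
    if scored:
        report = _score(scored)
        with open(output_dir / "metrics.json", "w") as fh:
            json.dump(report, fh, indent=2)
        summary["metrics"] = report
    return summary


def _score(scored) -> dict:
    dices, ious, preds, trues = [], [], [], []
    for res, gt in scored:
        if gt.shape != res.mask.shape:
            gt = (resize(gt.astype(np.float64),
                         target_size=res.mask.shape[0]) > 0.5).astype(np.uint8)
        dices.append(dice_score(res.mask, gt))
        ious.append(iou_score(res.mask, gt))
        preds.append(res.tumor_label)
        trues.append(int(gt.any()))
    rep = classification_report(preds, trues)
    return {"n": len(scored), "dice_mean": float(np.mean(dices)),
            "iou_mean": float(np.mean(ious)), "f1": rep.f1,
            "precision": rep.precision, "recall": rep.recall,
            "accuracy": rep.accuracy}


# ---------------------------------------------------------------------------
# bundle persistence


def save_bundle(bundle: ModelBundle, path) -> Path:
    """Write the four checkpoints plus a manifest JSON to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    bundle.view_classifier.save(path / _BUNDLE_FILES["classifier"])
    for view, model in bundle.per_view_models.items():
        model.save(path / _BUNDLE_FILES[ViewLabel(view)])
    clf_cfg = bundle.view_classifier.cfg
    any_seg = next(iter(bundle.per_view_models.values()))
    manifest = {
        "version": BUNDLE_VERSION,
        "image_size": clf_cfg.image_size,
        "header_mode": any_seg.cfg.header_mode,
        "files": {"classifier": _BUNDLE_FILES["classifier"],
                  **{v.name.lower(): _BUNDLE_FILES[v] for v in ViewLabel}},
    }
    with open(path / "bundle.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def load_bundle(path) -> ModelBundle:
    """Load a bundle directory; refuses incomplete or mismatched bundles."""
    path = Path(path)
    mpath = path / "bundle.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no bundle.json under {path}")
    with open(mpath) as fh:
        manifest = json.load(fh)
    if manifest.get("version") != BUNDLE_VERSION:
        raise ValueError(
            f"bundle version {manifest.get('version')} does not match "
            f"{BUNDLE_VERSION}; re-export the bundle with this release")
    missing = [v.name.lower() for v in ViewLabel
               if not (path / _BUNDLE_FILES[v]).exists()]
    if missing:
        raise FileNotFoundError(
            f"bundle is missing per-view model(s): {', '.join(missing)}")
    classifier = ViewClassifierModel.load(path / _BUNDLE_FILES["classifier"])
    per_view = {v: SegClassModel.load(path / _BUNDLE_FILES[v])
                for v in ViewLabel}
    sizes = {classifier.cfg.image_size} | {
        m.cfg.image_size for m in per_view.values()}
    if len(sizes) > 1:
        raise ValueError(f"inconsistent image sizes in bundle: {sizes}")
    modes = {m.cfg.header_mode for m in per_view.values()}
    if len(modes) > 1:
        raise ValueError(f"inconsistent header modes in bundle: {modes}")
    return ModelBundle(view_classifier=classifier, per_view_models=per_view)
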