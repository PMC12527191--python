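"""Model wrappers: the view classifier, the per-view segmentation network
with its tumor-presence header, and the routed model bundle.

The view classifier maps a slice to one of the three anatomical
orientations (axial = 0, coronal = 1, sagittal = 2).  Each per-view
segmentation model produces a single-channel logit map at input
resolution; its header converts the map (or pooled bottleneck features)
into one tumor-present/absent label per image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import IntEnum
from pathlib import Path

import numpy as np

from viewseg.nn.nets import ConvClassifier, UNetSegClass
from viewseg.nn.objectives import sigmoid

__all__ = [
    "ViewLabel",
    "ClassifierConfig",
    "SegClassConfig",
    "ViewClassifierModel",
    "SegClassModel",
    "ModelBundle",
    "build_view_classifier",
    "classify_view",
    "build_segclass_model",
    "segment",
    "detect",
]

CHECKPOINT_VERSION = 1


class ViewLabel(IntEnum):
    """Anatomical slice orientation codes."""

    AXIAL = 0
    CORONAL = 1
    SAGITTAL = 2


class ConfigError(ValueError):
    """Invalid model configuration."""


@dataclass(frozen=True)
class ClassifierConfig:
    image_size: int = 64
    in_channels: int = 3
    base_channels: int = 8
    n_stages: int = 3
    encoder: str = "small"

    def __post_init__(self):
        if self.encoder != "small":
            raise ConfigError(f"unknown encoder {self.encoder!r}; "
                              "available: 'small'")
        if self.image_size % 2 ** self.n_stages:
            raise ConfigError("image_size must be divisible by "
                              f"{2 ** self.n_stages}")


@dataclass(frozen=True)
class SegClassConfig:
    image_size: int = 64
    in_channels: int = 3
    base_channels: int = 8
    depth: int = 3
    encoder: str = "small"
    use_skips: bool = True
    header_mode: str = "mask-rule"     # or "learned"
    freeze_encoder: bool = False
    threshold: float = 0.65            # binarisation threshold for the header
    min_area_frac: float = 0.001       # minimum tumor area, fraction of pixels

    def __post_init__(self):
        if self.encoder != "small":
            raise ConfigError(f"unknown encoder {self.encoder!r}; "
                              "available: 'small'")
        if self.header_mode not in ("mask-rule", "learned"):
            raise ConfigError(f"unknown header mode {self.header_mode!r}")
        if self.image_size % 2 ** self.depth:
            raise ConfigError(
                f"image_size {self.image_size} not divisible by the "
                f"downsampling factor {2 ** self.depth}")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigError("threshold must lie in (0, 1)")


def _prepare_batch(images, in_channels: int) -> np.ndarray:
    """Stack (H, W) or (H, W, C) arrays into an NHWC float32 batch."""
    batch = []
    for im in images:
        a = np.asarray(im, dtype=np.float32)
        if a.ndim == 2:
            a = np.repeat(a[..., None], in_channels, axis=2)
        if a.ndim != 3 or a.shape[2] != in_channels:
            raise ValueError(
                f"expected {in_channels}-channel input, got shape {a.shape}")
        batch.append(a)
    return np.stack(batch)


@dataclass
class ViewClassifierModel:
    net: ConvClassifier
    cfg: ClassifierConfig
    seed: int = 0

    def logits(self, images, train: bool = False) -> np.ndarray:
        x = _prepare_batch(images, self.cfg.in_channels)
        return self.net.forward(x, train=train)

    def param_count(self) -> int:
        return self.net.param_count()

    def save(self, path) -> None:
        _save_checkpoint(path, self.net.state_dict(), asdict(self.cfg),
                         kind="classifier", seed=self.seed)

    @classmethod
    def load(cls, path) -> "ViewClassifierModel":
        state, cfg_dict, seed = _load_checkpoint(path, kind="classifier")
        cfg = ClassifierConfig(**cfg_dict)
        model = build_view_classifier(cfg, seed=seed)
        model.net.load_state_dict(state)
        return model


@dataclass
class SegClassModel:
    net: UNetSegClass
    cfg: SegClassConfig
    seed: int = 0
    view: ViewLabel | None = None

    def forward(self, images, train: bool = False):
        x = _prepare_batch(images, self.cfg.in_channels)
        return self.net.forward(x, train=train)

    def param_count(self) -> int:
        return self.net.param_count()

    def save(self, path) -> None:
        cfg = asdict(self.cfg)
        cfg["view"] = int(self.view) if self.view is not None else None
        _save_checkpoint(path, self.net.state_dict(), cfg,
                         kind="segclass", seed=self.seed)

    @classmethod
    def load(cls, path) -> "SegClassModel":
        state, cfg_dict, seed = _load_checkpoint(path, kind="segclass")
        view = cfg_dict.pop("view", None)
        cfg = SegClassConfig(**cfg_dict)
        model = build_segclass_model(cfg, seed=seed)
        model.net.load_state_dict(state)
        model.view = ViewLabel(view) if view is not None else None
        return model


@dataclass
class ModelBundle:
    """The view classifier plus one segmentation model per orientation."""

    view_classifier: ViewClassifierModel
    per_view_models: dict[ViewLabel, SegClassModel] = field(default_factory=dict)

    def __post_init__(self):
        missing = [v.name.lower() for v in ViewLabel
                   if v not in self.per_view_models]
        if missing:
            raise ValueError(
                f"bundle is missing per-view models: {', '.join(missing)}")


# ---------------------------------------------------------------------------
# build / apply


def build_view_classifier(cfg: ClassifierConfig | None = None, *,
                          seed: int = 0) -> ViewClassifierModel:
    cfg = cfg or ClassifierConfig()
    net = ConvClassifier(in_channels=cfg.in_channels,
                         base_channels=cfg.base_channels,
                         n_classes=3, n_stages=cfg.n_stages, seed=seed)
    return ViewClassifierModel(net=net, cfg=cfg, seed=seed)


def classify_view(model: ViewClassifierModel, image) -> ViewLabel:
    """Argmax over softmax of the classifier logits; ties break toward the
    lowest view code."""
    logits = model.logits([image])
    return ViewLabel(int(np.argmax(logits[0])))


def build_segclass_model(cfg: SegClassConfig | None = None, *,
                         seed: int = 0,
                         view: ViewLabel | None = None) -> SegClassModel:
    cfg = cfg or SegClassConfig()
    net = UNetSegClass(in_channels=cfg.in_channels,
                       base_channels=cfg.base_channels, depth=cfg.depth,
                       use_skips=cfg.use_skips,
                       with_head=True, seed=seed)
    return SegClassModel(net=net, cfg=cfg, seed=seed, view=view)


def segment(model: SegClassModel, image) -> np.ndarray:
    """Sigmoid probability map of one image, same spatial size as input."""
    seg_logits, _ = model.forward([image])
    return sigmoid(seg_logits[0]).astype(np.float32)


def detect(probmap, mode: str = "mask-rule", *, threshold: float = 0.65,
           min_area_frac: float = 0.001, head_logit=None) -> int:
    """Tumor-presence decision from a segmentation probability map.

    mask-rule (default)
        Label 1 iff the number of pixels at or above ``threshold`` is at
        least ``min_area_frac`` of the image (minimum 1 pixel).
    learned
        Label 1 iff ``sigmoid(head_logit) >= 0.5``.
    """
    if mode == "mask-rule":
        p = np.asarray(probmap, dtype=np.float64)
        a_min = max(1, int(np.ceil(min_area_frac * p.size)))
        return int((p >= threshold).sum() >= a_min)
    if mode == "learned":
        if head_logit is None:
            raise ValueError("learned mode requires the head logit")
        return int(sigmoid(np.asarray([head_logit], dtype=np.float64))[0]
                   >= 0.5)
    raise ConfigError(f"unknown detection mode {mode!r}")


# ---------------------------------------------------------------------------
# checkpoints


def _save_checkpoint(path, state: dict, cfg: dict, *, kind: str,
                     seed: int) -> None:
    meta = json.dumps({"version": CHECKPOINT_VERSION, "kind": kind,
                       "seed": seed, "config": cfg})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **state)


def _load_checkpoint(path, *, kind: str):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"checkpoint version {meta.get('version')} does not match "
                f"{CHECKPOINT_VERSION}; re-train or convert the checkpoint")
        if meta.get("kind") != kind:
            raise ValueError(f"checkpoint kind {meta.get('kind')!r} is not "
                             f"{kind!r}")
        state = {k: data[k] for k in data.files if k != "__meta__"}
    return state, meta["config"], meta.get("seed", 0)
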