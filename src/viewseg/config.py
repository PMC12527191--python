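"""Single-YAML run configuration with sections
``data``, ``augment``, ``model``, ``loss``, ``train`` and ``eval``."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from viewseg.losses import LossConfig
from viewseg.models import ClassifierConfig, SegClassConfig
from viewseg.preprocess import AugmentConfig
from viewseg.training import TrainConfig

DEFAULTS: dict = {
    "data": {
        "image_size": 64,
        "n_per_view": 300,
        "tumor_rate": 0.7,
        "noise_sigma": 0.03,
        "view_mix": [1 / 3, 1 / 3, 1 / 3],
        "split": [0.8, 0.1, 0.1],
        "seed": 0,
    },
    "augment": {
        "theta_max": 10.0,
        "affine_degrees": 5.0,
        "affine_translate": [0.05, 0.05],
        "affine_scale": [0.95, 1.05],
        "affine_shear": 5.0,
        "enabled_for": ["classifier"],
        "mean": 0.5,
        "std": 0.5,
    },
    "model": {
        "encoder": "small",
        "base_channels": 8,
        "depth": 3,
        "header_mode": "mask-rule",
        "freeze_encoder": False,
        "min_area_frac": 0.001,
    },
    "loss": {"w": 0.4, "alpha": 0.7, "beta": 0.3, "gamma": 0.7,
             "lambda": 0.2, "epsilon": 1e-6},
    "train": {
        "classifier": {"epochs": 30, "batch_size": 16,
                       "learning_rate": 1e-5, "weight_decay": 0.05},
        "segmentation": {"epochs": 20, "batch_size": 3,
                         "learning_rate": 1e-3, "weight_decay": 0.0},
        "seed": 0,
    },
    "eval": {"threshold": 0.65},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path=None) -> dict:
    """Defaults, overlaid with the YAML file at ``path`` when given."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(Path(path)) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULTS, user)


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# -- typed views over the dict ----------------------------------------------


def loss_config(cfg: dict) -> LossConfig:
    l = cfg["loss"]
    return LossConfig(w=l["w"], alpha=l["alpha"], beta=l["beta"],
                      gamma=l["gamma"], lam=l["lambda"], eps=l["epsilon"])


def augment_config(cfg: dict) -> AugmentConfig:
    a = cfg["augment"]
    return AugmentConfig(
        theta_max=a["theta_max"], affine_degrees=a["affine_degrees"],
        affine_translate=tuple(a["affine_translate"]),
        affine_scale=tuple(a["affine_scale"]),
        affine_shear=a["affine_shear"],
        target_size=cfg["data"]["image_size"],
        enabled_for=tuple(a["enabled_for"]), mean=a["mean"], std=a["std"])


def classifier_model_config(cfg: dict) -> ClassifierConfig:
    return ClassifierConfig(image_size=cfg["data"]["image_size"],
                            base_channels=cfg["model"]["base_channels"],
                            encoder=cfg["model"]["encoder"])


def segclass_model_config(cfg: dict) -> SegClassConfig:
    m = cfg["model"]
    return SegClassConfig(
        image_size=cfg["data"]["image_size"],
        base_channels=m["base_channels"], depth=m["depth"],
        encoder=m["encoder"], header_mode=m["header_mode"],
        freeze_encoder=m["freeze_encoder"],
        threshold=cfg["eval"]["threshold"],
        min_area_frac=m["min_area_frac"])


def train_config(cfg: dict, task: str, **overrides) -> TrainConfig:
    t = dict(cfg["train"][task])
    t.update(overrides)
    return TrainConfig(
        epochs=t["epochs"], batch_size=t["batch_size"],
        learning_rate=t["learning_rate"], weight_decay=t["weight_decay"],
        seed=t.get("seed", cfg["train"]["seed"]),
        loss=loss_config(cfg), augment=augment_config(cfg),
        freeze_encoder=cfg["model"]["freeze_encoder"])
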