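"""Shared fixtures.

The heavier fixtures (trained models) are session-scoped so several tests
can share one training run; everything is seeded, so the suite is
deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from viewseg.losses import LossConfig
from viewseg.models import (
    ClassifierConfig,
    ModelBundle,
    SegClassConfig,
    ViewLabel,
    build_segclass_model,
    build_view_classifier,
)
from viewseg.phantoms import PhantomSpec, generate_dataset, split_dataset
from viewseg.training import TrainConfig, train_segclass

# Desk-scale study conditions: 64x64 phantoms, small scratch encoder
# (base width 6, three pooling stages), AdamW.
IMAGE_SIZE = 64
BASE_CHANNELS = 6
SEG_TRAIN = dict(epochs=15, batch_size=8, learning_rate=1e-3,
                 weight_decay=0.0)
CLF_TRAIN = dict(epochs=12, batch_size=16, learning_rate=3e-3,
                 weight_decay=0.05)


def make_phantom_set(n: int, seed: int, view: ViewLabel | None = None,
                     tumor_rate: float = 0.7):
    """Generate and 80-10-10 split a phantom dataset."""
    mix = (1 / 3, 1 / 3, 1 / 3) if view is None else tuple(
        1.0 if v == view else 0.0 for v in ViewLabel)
    samples = generate_dataset(
        n, view_mix=mix, tumor_rate=tumor_rate,
        template=PhantomSpec(image_size=IMAGE_SIZE), seed=seed)
    return split_dataset(samples, seed=seed)


def seg_config(**overrides) -> SegClassConfig:
    base = dict(image_size=IMAGE_SIZE, base_channels=BASE_CHANNELS)
    base.update(overrides)
    return SegClassConfig(**base)


def train_one_view(view: ViewLabel, seed: int, n: int = 300,
                   loss: LossConfig | None = None, **cfg_overrides):
    """Train one per-view model under the standard study conditions."""
    train, val, test = make_phantom_set(n, seed=1000 + seed, view=view)
    tcfg = TrainConfig(seed=seed, loss=loss or LossConfig(), **SEG_TRAIN)
    model = build_segclass_model(seg_config(**cfg_overrides), seed=seed,
                                 view=view)
    model, history = train_segclass(model, train, val, tcfg)
    return model, history, test


@pytest.fixture(scope="session")
def tiny_bundle():
    """An untrained (random-weight) bundle for pipeline plumbing tests."""
    clf = build_view_classifier(
        ClassifierConfig(image_size=IMAGE_SIZE, base_channels=4), seed=7)
    per_view = {v: build_segclass_model(seg_config(base_channels=4),
                                        seed=10 + int(v), view=v)
                for v in ViewLabel}
    return ModelBundle(view_classifier=clf, per_view_models=per_view)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
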