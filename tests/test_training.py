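"""Training loops: reproducibility, loss bookkeeping, evaluation, sweeps.

Runs here are deliberately tiny (tens of phantoms, a few epochs); the
full phantom-recovery runs live in the acceptance suite.
"""

import numpy as np
import pytest

from viewseg.losses import LossConfig
from viewseg.models import (
    SegClassConfig,
    ViewLabel,
    build_segclass_model,
    build_view_classifier,
    ClassifierConfig,
)
from viewseg.phantoms import PhantomSpec, generate_dataset, split_dataset
from viewseg.training import (
    TrainConfig,
    evaluate,
    predict_probmaps,
    sweep,
    train_segclass,
    train_view_classifier,
)


def tiny_view_data(n=12, view=ViewLabel.AXIAL, seed=0, tumor_rate=0.7):
    mix = tuple(1.0 if v == view else 0.0 for v in ViewLabel)
    return generate_dataset(n, view_mix=mix, tumor_rate=tumor_rate,
                            template=PhantomSpec(image_size=64), seed=seed)


def tiny_cfg(**kw):
    base = dict(epochs=1, batch_size=4, learning_rate=1e-3, seed=0,
                loss=LossConfig())
    base.update(kw)
    return TrainConfig(**base)


class TestTrainViewClassifier:
    def test_history_length_matches_epochs(self):
        data = generate_dataset(10, seed=1)
        clf = build_view_classifier(ClassifierConfig(base_channels=4), seed=0)
        _, hist = train_view_classifier(clf, data, [], tiny_cfg())
        assert len(hist) == 1

    def test_empty_data_rejected(self):
        clf = build_view_classifier(ClassifierConfig(base_channels=4), seed=0)
        with pytest.raises(ValueError):
            train_view_classifier(clf, [], [], tiny_cfg())

    def test_loss_decreases_over_training(self):
        data = generate_dataset(60, seed=2)
        clf = build_view_classifier(ClassifierConfig(base_channels=4), seed=0)
        _, hist = train_view_classifier(clf, data, [],
                                        tiny_cfg(epochs=5, batch_size=8,
                                                 learning_rate=3e-3))
        assert hist.rows[-1]["train_loss"] < hist.rows[0]["train_loss"]

    def test_fixed_seed_reproduces_loss_sequence(self):
        data = generate_dataset(20, seed=3)
        runs = []
        for _ in range(2):
            clf = build_view_classifier(ClassifierConfig(base_channels=4),
                                        seed=0)
            _, hist = train_view_classifier(clf, data, [],
                                            tiny_cfg(epochs=2))
            runs.append([r["train_loss"] for r in hist.rows])
        assert runs[0] == runs[1]

    def test_class_weighting_helps_minority_recall(self):
        """With a 10:1:1 view imbalance, inverse-frequency weighting gives
        minority-class recall at least as high as the unweighted run."""
        data = generate_dataset(120, view_mix=(10 / 12, 1 / 12, 1 / 12),
                                seed=4)
        test = generate_dataset(60, view_mix=(0, 0.5, 0.5), seed=5)
        recalls = {}
        for weighting in (True, False):
            clf = build_view_classifier(
                ClassifierConfig(base_channels=4), seed=0)
            clf, _ = train_view_classifier(
                clf, data, [], tiny_cfg(epochs=6, batch_size=16,
                                        learning_rate=3e-3,
                                        class_weighting=weighting))
            correct = total = 0
            for s in test:
                from viewseg.models import classify_view
                from viewseg.preprocess import normalize
                pred = classify_view(clf, normalize(s.image))
                correct += int(pred == s.view)
                total += 1
            recalls[weighting] = correct / total
        assert recalls[True] >= recalls[False]


class TestTrainSegClass:
    def test_mixed_views_rejected_when_strict(self):
        data = generate_dataset(12, seed=6)  # mixed views
        model = build_segclass_model(SegClassConfig(base_channels=4), seed=0)
        with pytest.raises(ValueError, match="mixed views"):
            train_segclass(model, data, [], tiny_cfg())

    def test_step_log_satisfies_total_identity(self):
        """Logged total equals (1-lambda)*seg + lambda*cls at every step."""
        data = tiny_view_data(8, seed=7)
        model = build_segclass_model(SegClassConfig(base_channels=4), seed=0)
        cfg = tiny_cfg(epochs=2)
        _, hist = train_segclass(model, data, [], cfg)
        lam = cfg.loss.lam
        for step in hist.steps:
            assert step["total"] == pytest.approx(
                (1 - lam) * step["seg"] + lam * step["cls"], abs=1e-9)

    def test_lambda_zero_equals_headerless_training(self):
        """At lambda = 0 the objective reduces to the pure segmentation
        loss, so the header mode (parameter-free vs learned) cannot change
        the per-step loss sequence."""
        data = tiny_view_data(8, seed=8)
        seqs = []
        for mode in ("mask-rule", "learned"):
            model = build_segclass_model(
                SegClassConfig(base_channels=4, header_mode=mode), seed=0)
            _, hist = train_segclass(
                model, data, [], tiny_cfg(epochs=2,
                                          loss=LossConfig(lam=0.0)))
            seqs.append([s["total"] for s in hist.steps])
        assert seqs[0] == seqs[1]

    def test_best_checkpoint_by_validation_dice(self):
        data = tiny_view_data(16, seed=9)
        model = build_segclass_model(SegClassConfig(base_channels=4), seed=0)
        _, hist = train_segclass(model, data[:12], data[12:],
                                 tiny_cfg(epochs=3))
        dices = [r["val_dice"] for r in hist.rows]
        assert hist.best_epoch == int(np.argmax(dices))

    def test_seeded_run_is_reproducible(self):
        data = tiny_view_data(8, seed=10)
        outs = []
        for _ in range(2):
            model = build_segclass_model(SegClassConfig(base_channels=4),
                                         seed=1)
            model, hist = train_segclass(model, data, [], tiny_cfg(epochs=2))
            outs.append((tuple(r["train_loss"] for r in hist.rows),
                         model.net.state_dict()["final.W"].copy()))
        assert outs[0][0] == outs[1][0]
        np.testing.assert_array_equal(outs[0][1], outs[1][1])


class TestEvaluate:
    def test_oracle_predictions_score_one(self, monkeypatch):
        import viewseg.training as T
        data = tiny_view_data(6, seed=11)
        model = build_segclass_model(SegClassConfig(base_channels=4),
                                     seed=0, view=ViewLabel.AXIAL)

        def oracle(model_, samples, batch=16):
            return [s.mask.astype(np.float32) for s in samples], None
        monkeypatch.setattr(T, "predict_probmaps", oracle)
        res = T.evaluate(model, data)
        o = res["overall"]
        assert o.iou == o.dice == o.f1 == o.accuracy == 1.0

    def test_constant_background_model_fails_tumor_cases(self):
        data = [s for s in tiny_view_data(10, seed=12, tumor_rate=1.0)]
        model = build_segclass_model(SegClassConfig(base_channels=4), seed=0)
        model.net.final.W.value[:] = 0.0
        model.net.final.b.value[:] = -10.0
        res = evaluate(model, data)
        assert res["overall"].dice < 0.01
        assert res["overall"].recall == 0.0

    def test_empty_data_rejected(self):
        model = build_segclass_model(SegClassConfig(base_channels=4), seed=0)
        with pytest.raises(ValueError):
            evaluate(model, [])

    def test_evaluate_matches_standalone_metrics(self):
        """Metrics from evaluate equal metrics recomputed from the saved
        probability maps with the standalone metrics module."""
        from viewseg.metrics import binarize, dice_score, iou_score
        data = tiny_view_data(6, seed=13)
        model = build_segclass_model(SegClassConfig(base_channels=4),
                                     seed=3, view=ViewLabel.AXIAL)
        res = evaluate(model, data, tau=0.65)
        probs, _ = predict_probmaps(model, data)
        for row, prob, s in zip(res["rows"], probs, data):
            pred = binarize(prob, 0.65)
            assert row["dice"] == pytest.approx(dice_score(pred, s.mask))
            assert row["iou"] == pytest.approx(iou_score(pred, s.mask))


class TestSweep:
    def test_single_threshold_value_matches_plain_evaluate(self):
        samples = tiny_view_data(20, seed=14)
        data = split_dataset(samples, seed=14)
        cfg = tiny_cfg(epochs=1)
        table = sweep("threshold", [0.65], cfg, data, seeds=[0],
                      model_cfg=SegClassConfig(base_channels=4))
        model = build_segclass_model(SegClassConfig(base_channels=4), seed=0)
        model, _ = train_segclass(model, data[0], data[1], cfg)
        res = evaluate(model, data[2], tau=0.65)
        assert table.iloc[0]["dice"] == pytest.approx(res["overall"].dice)

    def test_threshold_sweep_trains_once_per_seed(self, monkeypatch):
        import viewseg.training as T
        calls = {"n": 0}
        orig = T.train_segclass

        def counting(*a, **k):
            calls["n"] += 1
            return orig(*a, **k)
        monkeypatch.setattr(T, "train_segclass", counting)
        samples = tiny_view_data(16, seed=15)
        data = split_dataset(samples, seed=15)
        T.sweep("threshold", [0.5, 0.65, 0.8], tiny_cfg(), data, seeds=[0],
                model_cfg=SegClassConfig(base_channels=4))
        assert calls["n"] == 1

    def test_empty_values_rejected(self):
        with pytest.raises(ValueError):
            sweep("lambda", [], tiny_cfg(), ([], [], []), seeds=[0])

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            sweep("dropout", [0.1], tiny_cfg(), ([], [], []), seeds=[0])
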