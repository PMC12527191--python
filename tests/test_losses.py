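"""Loss functions against closed forms and independent scalar-loop oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from viewseg.losses import (
    LossConfig,
    bce_logit_loss,
    class_weights,
    classification_loss,
    dice_loss,
    iou_loss,
    segmentation_loss,
    softmax,
    total_loss,
    tversky_loss,
    weighted_cross_entropy,
)

# ---------------------------------------------------------------------------
# scalar double-loop oracles (kept deliberately naive and separate from the
# vectorised implementations)


def oracle_dice(o, g, eps):
    inter = s_o = s_g = 0.0
    for i in range(o.shape[0]):
        for j in range(o.shape[1]):
            inter += o[i, j] * g[i, j]
            s_o += o[i, j]
            s_g += g[i, j]
    return 1.0 - (2.0 * inter + eps) / (s_o + s_g + eps)


def oracle_tversky(o, g, a, b, eps):
    tp = fn = fp = 0.0
    for i in range(o.shape[0]):
        for j in range(o.shape[1]):
            tp += o[i, j] * g[i, j]
            fn += (1.0 - o[i, j]) * g[i, j]
            fp += o[i, j] * (1.0 - g[i, j])
    return 1.0 - (tp + eps) / (tp + a * fn + b * fp + eps)


def oracle_iou(o, g, eps):
    inter = s_o = s_g = 0.0
    for i in range(o.shape[0]):
        for j in range(o.shape[1]):
            inter += o[i, j] * g[i, j]
            s_o += o[i, j]
            s_g += g[i, j]
    return 1.0 - (inter + eps) / (s_o + s_g - inter + eps)


def oracle_bce(p, t):
    total = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            total += np.log(1.0 + np.exp(-p[i, j])) + p[i, j] * (1.0 - t[i, j])
    return total / p.size


def oracle_softmax(z):
    e = [np.exp(v) for v in z]
    s = sum(e)
    return [v / s for v in e]


def oracle_wce(z, k, w):
    s = oracle_softmax(z)
    return -w[k] * np.log(s[k])


# ---------------------------------------------------------------------------


class TestSoftmax:
    def test_symmetry_and_closed_form(self):
        np.testing.assert_allclose(softmax([0.0, 0.0, 0.0]), [1 / 3] * 3)
        np.testing.assert_allclose(
            softmax([1.0, 0.0]),
            [np.e / (np.e + 1), 1 / (np.e + 1)], rtol=1e-12)

    def test_shift_invariance(self, rng):
        z = rng.normal(size=7)
        np.testing.assert_allclose(softmax(z), softmax(z + 123.456),
                                   atol=1e-12)

    def test_overflow_safety(self):
        out = softmax([1e4, 0.0])
        assert np.isfinite(out).all() and abs(out.sum() - 1) < 1e-12

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            softmax([np.inf, 0.0])


class TestClassWeights:
    def test_inverse_frequency(self):
        w = class_weights([1010, 965, 963])
        np.testing.assert_allclose(w, [2938 / 1010, 2938 / 965, 2938 / 963])
        np.testing.assert_allclose(w, [2.9089, 3.0446, 3.0509], atol=5e-5)

    def test_balanced_counts_give_class_count(self):
        np.testing.assert_allclose(class_weights([7, 7, 7]), [3, 3, 3])

    def test_two_class_extreme(self):
        np.testing.assert_allclose(class_weights([1, 999]),
                                   [1000.0, 1000 / 999])

    @pytest.mark.parametrize("bad", [[0, 5], [-1, 5], []])
    def test_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            class_weights(bad)


class TestWeightedCrossEntropy:
    def test_closed_form(self):
        # probabilities [0.5, 0.25, 0.25] from logits log of those values
        z = np.log([0.5, 0.25, 0.25])
        val = weighted_cross_entropy(z, 0, [2.0, 1.0, 1.0])
        assert val == pytest.approx(2 * np.log(2), rel=1e-12)

    def test_confident_correct_prediction_vanishes(self):
        val = weighted_cross_entropy([50.0, 0.0, 0.0], 0, [1.0, 1.0, 1.0])
        assert val < 1e-9

    def test_uniform_weights_match_plain_ce(self, rng):
        z = rng.normal(size=3)
        plain = -np.log(softmax(z))[1]
        assert weighted_cross_entropy(z, 1, [1.0] * 3) == pytest.approx(plain)

    def test_rejects_out_of_range_class(self):
        with pytest.raises(ValueError):
            weighted_cross_entropy([0.0, 0.0], 2, [1.0, 1.0])


class TestOverlapLosses:
    def test_perfect_match_is_zero(self):
        v = np.array([1.0, 0.0, 1.0])
        assert dice_loss(v, v) == pytest.approx(0.0, abs=1e-6)
        assert tversky_loss(v, v) == pytest.approx(0.0, abs=1e-6)
        assert iou_loss(v, v) == pytest.approx(0.0, abs=1e-6)

    def test_empty_vs_empty_is_zero(self):
        z = np.zeros((4, 4))
        assert dice_loss(z, z) == 0.0
        assert iou_loss(z, z) == 0.0

    def test_hand_counted_example(self):
        o = np.array([1.0, 1.0, 0.0, 0.0])
        g = np.array([1.0, 0.0, 1.0, 0.0])
        assert dice_loss(o, g, eps=0) == pytest.approx(0.5)
        assert tversky_loss(o, g, 0.7, 0.3, eps=0) == pytest.approx(0.5)
        assert iou_loss(o, g, eps=0) == pytest.approx(2 / 3)

    def test_disjoint_masks_lose_everything(self):
        o = np.array([[1.0, 0.0], [1.0, 0.0]])
        g = np.array([[0.0, 1.0], [0.0, 1.0]])
        assert iou_loss(o, g) == pytest.approx(1.0, abs=1e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            tversky_loss(np.zeros(3), np.zeros(4))
        with pytest.raises(ValueError):
            iou_loss(np.zeros(3), np.zeros(4))

    def test_negative_tversky_weights_rejected(self):
        with pytest.raises(ValueError):
            tversky_loss(np.zeros(3), np.zeros(3), alpha=-0.1)

    def test_batch_reduction_is_mean_of_per_image(self, rng):
        o = rng.random((3, 5, 5))
        g = (rng.random((3, 5, 5)) < 0.4).astype(float)
        per = [dice_loss(o[k], g[k]) for k in range(3)]
        assert dice_loss(o, g) == pytest.approx(np.mean(per), rel=1e-12)


class TestBCE:
    def test_zero_logit_gives_log_two(self):
        assert bce_logit_loss([0.0], [1.0]) == pytest.approx(np.log(2))
        assert bce_logit_loss([0.0], [0.0]) == pytest.approx(np.log(2))

    def test_saturation_limit(self):
        assert bce_logit_loss([60.0], [1.0]) < 1e-9

    def test_stable_at_large_negative_logits(self):
        assert np.isfinite(bce_logit_loss([-1000.0], [0.0]))


class TestComposites:
    def test_weight_one_reduces_to_dice(self, rng):
        o = rng.random((6, 6))
        g = (rng.random((6, 6)) < 0.3).astype(float)
        cfg = LossConfig(w=1.0)
        assert segmentation_loss(o, g, cfg) == pytest.approx(
            dice_loss(o, g, eps=cfg.eps))

    def test_arithmetic_examples(self):
        cfg = LossConfig(w=0.4)
        assert 0.4 * 0.2 + 0.6 * 0.6 == pytest.approx(0.44)
        assert total_loss(0.5, 0.6852, LossConfig(lam=0.2)) == pytest.approx(
            0.8 * 0.5 + 0.2 * 0.6852)

    def test_table_defaults_on_hand_example(self):
        o = np.array([1.0, 1.0, 0.0, 0.0])
        g = np.array([1.0, 0.0, 1.0, 0.0])
        cfg = LossConfig(eps=1e-12)
        # both components equal 0.5 on this pair, so any w gives 0.5
        assert segmentation_loss(o, g, cfg) == pytest.approx(0.5, abs=1e-9)

    def test_gamma_endpoints(self, rng):
        z = rng.normal(size=(5, 5))
        o = 1 / (1 + np.exp(-z))
        g = (rng.random((5, 5)) < 0.4).astype(float)
        c1 = classification_loss(z, o, g, LossConfig(gamma=1.0))
        assert c1 == pytest.approx(bce_logit_loss(z, g))
        c0 = classification_loss(z, o, g, LossConfig(gamma=0.0))
        assert c0 == pytest.approx(iou_loss(o, g, eps=1e-6))

    def test_lambda_endpoints_exact(self):
        assert total_loss(0.37, 0.91, LossConfig(lam=0.0)) == 0.37
        assert total_loss(0.37, 0.91, LossConfig(lam=1.0)) == 0.91

    def test_config_validation(self):
        with pytest.raises(ValueError):
            LossConfig(lam=1.5)
        with pytest.raises(ValueError):
            LossConfig(alpha=-1)
        with pytest.raises(ValueError):
            LossConfig(eps=0)


# ---------------------------------------------------------------------------
# property tests


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.floats(0.0, 1.0), st.floats(0.0, 1.0))
def test_composites_are_convex_combinations(seed, a, b):
    """Composite losses always lie between their components."""
    rng = np.random.default_rng(seed)
    o = rng.random((4, 4))
    g = (rng.random((4, 4)) < 0.5).astype(float)
    z = rng.normal(size=(4, 4))
    cfg = LossConfig(w=a, gamma=b, lam=a)
    ld, lt = dice_loss(o, g), tversky_loss(o, g, cfg.alpha, cfg.beta)
    ls = segmentation_loss(o, g, cfg)
    assert min(ld, lt) - 1e-12 <= ls <= max(ld, lt) + 1e-12
    lb, li = bce_logit_loss(z, g), iou_loss(1 / (1 + np.exp(-z)), g)
    lc = classification_loss(z, 1 / (1 + np.exp(-z)), g, cfg)
    assert min(lb, li) - 1e-12 <= lc <= max(lb, li) + 1e-12
    lt_total = total_loss(ls, lc, cfg)
    assert min(ls, lc) - 1e-12 <= lt_total <= max(ls, lc) + 1e-12


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_tversky_dice_identity_and_transpose(seed):
    """Tversky(0.5, 0.5) = Dice; swapping the maps swaps alpha and beta."""
    rng = np.random.default_rng(seed)
    o = (rng.random((6, 6)) < 0.4).astype(float)
    g = (rng.random((6, 6)) < 0.4).astype(float)
    eps = 1e-6
    assert tversky_loss(o, g, 0.5, 0.5, eps) == pytest.approx(
        dice_loss(o, g, eps), abs=10 * eps)
    a, b = 0.8, 0.15
    assert tversky_loss(o, g, a, b, eps) == pytest.approx(
        tversky_loss(g, o, b, a, eps), abs=1e-9)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_tversky_monotone_in_alpha_and_beta(seed):
    rng = np.random.default_rng(seed)
    o = rng.random((5, 5))
    g = (rng.random((5, 5)) < 0.5).astype(float)
    if ((1 - o) * g).sum() == 0 or (o * (1 - g)).sum() == 0:
        return
    la = [tversky_loss(o, g, a, 0.3) for a in (0.1, 0.5, 1.0)]
    assert la[0] <= la[1] <= la[2]
    lb = [tversky_loss(o, g, 0.7, b) for b in (0.1, 0.5, 1.0)]
    assert lb[0] <= lb[1] <= lb[2]


def test_all_losses_match_scalar_oracles():
    """200 random 8x8 pairs: every loss matches its double-loop oracle to
    1e-9."""
    rng = np.random.default_rng(99)
    cfg = LossConfig()
    for _ in range(200):
        o = rng.random((8, 8))
        g = (rng.random((8, 8)) < rng.uniform(0.1, 0.9)).astype(float)
        z = rng.normal(0, 3, (8, 8))
        eps = 1e-6
        assert dice_loss(o, g, eps) == pytest.approx(
            oracle_dice(o, g, eps), abs=1e-9)
        assert tversky_loss(o, g, cfg.alpha, cfg.beta, eps) == pytest.approx(
            oracle_tversky(o, g, cfg.alpha, cfg.beta, eps), abs=1e-9)
        assert iou_loss(o, g, eps) == pytest.approx(
            oracle_iou(o, g, eps), abs=1e-9)
        assert bce_logit_loss(z, g) == pytest.approx(oracle_bce(z, g),
                                                     abs=1e-9)
        assert segmentation_loss(o, g, cfg) == pytest.approx(
            cfg.w * oracle_dice(o, g, cfg.eps)
            + (1 - cfg.w) * oracle_tversky(o, g, cfg.alpha, cfg.beta, cfg.eps),
            abs=1e-9)
        sig = 1 / (1 + np.exp(-z))
        assert classification_loss(z, sig, g, cfg) == pytest.approx(
            cfg.gamma * oracle_bce(z, g)
            + (1 - cfg.gamma) * oracle_iou(sig, g, cfg.eps), abs=1e-9)
        zc = rng.normal(0, 2, 3)
        k = int(rng.integers(3))
        w = class_weights(rng.integers(1, 50, 3))
        assert weighted_cross_entropy(zc, k, w) == pytest.approx(
            oracle_wce(zc, k, w), abs=1e-9)
        np.testing.assert_allclose(softmax(zc), oracle_softmax(zc),
                                   atol=1e-9)
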