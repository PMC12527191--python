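"""Network definitions: a small convolutional classifier and a U-Net-style
encoder-decoder with skip connections and an optional classification head.

Both networks hand-wire their backward passes through the layer primitives,
keeping the whole stack dependency-free and bit-reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from viewseg.nn.layers import (
    DTYPE,
    Conv2d,
    Dense,
    Param,
    global_avg_pool,
    global_avg_pool_backward,
    maxpool2,
    maxpool2_backward,
    relu,
    relu_backward,
    upsample2,
    upsample2_backward,
)


def _named_params(layers: dict) -> dict[str, Param]:
    out = {}
    for name, layer in layers.items():
        out[f"{name}.W"] = layer.W
        out[f"{name}.b"] = layer.b
    return out


class ConvClassifier:
    """conv-relu-pool x3 -> global average pool -> dense logits."""

    def __init__(self, in_channels: int = 3, base_channels: int = 8,
                 n_classes: int = 3, n_stages: int = 3, *, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_classes = n_classes
        self.in_channels = in_channels
        chans = [in_channels] + [base_channels * 2 ** i for i in range(n_stages)]
        self.convs = [Conv2d(chans[i], chans[i + 1], rng=rng)
                      for i in range(n_stages)]
        self.fc = Dense(chans[-1], n_classes, rng=rng)
        self._cache = None

    # -- parameters ---------------------------------------------------------
    def _layers(self) -> dict:
        d = {f"conv{i}": c for i, c in enumerate(self.convs)}
        d["fc"] = self.fc
        return d

    def params(self) -> list[Param]:
        return [p for l in self._layers().values() for p in l.params()]

    def param_count(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.value.copy() for k, p in _named_params(self._layers()).items()}

    def load_state_dict(self, state: dict) -> None:
        named = _named_params(self._layers())
        for k, p in named.items():
            p.value = np.asarray(state[k], dtype=DTYPE).copy()

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[3] != self.in_channels:
            raise ValueError(
                f"expected NHWC input with {self.in_channels} channels, "
                f"got shape {x.shape}")
        caches = []
        a = x.astype(DTYPE, copy=False)
        for conv in self.convs:
            h = conv.forward(a, train=train)
            h, rm = relu(h)
            a, pm = maxpool2(h)
            caches.append((rm, pm))
        pooled = global_avg_pool(a)
        logits = self.fc.forward(pooled, train=train)
        if train:
            self._cache = (caches, a.shape)
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        caches, gap_shape = self._cache
        d = self.fc.backward(dlogits.astype(DTYPE, copy=False))
        d = global_avg_pool_backward(d, gap_shape)
        for conv, (rm, pm) in zip(reversed(self.convs), reversed(caches)):
            d = maxpool2_backward(d, pm)
            d = relu_backward(d, rm)
            d = conv.backward(d)
        self._cache = None


class UNetSegClass:
    """Encoder-decoder segmentation network with a tumor-presence head.

    ``depth`` pooling stages halve the resolution; the decoder mirrors the
    encoder and (optionally) concatenates the matching encoder activation
    before each decoder convolution.  The segmentation output is a single
    logit map at input resolution; the head is a dense layer over the
    globally pooled bottleneck features emitting one logit per image.
    """

    def __init__(self, in_channels: int = 3, base_channels: int = 8,
                 depth: int = 3, use_skips: bool = True,
                 with_head: bool = True, *, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.depth = depth
        self.use_skips = use_skips
        self.with_head = with_head
        c = base_channels
        enc_ch = [in_channels] + [c * 2 ** i for i in range(depth)]
        self.enc = [Conv2d(enc_ch[i], enc_ch[i + 1], rng=rng)
                    for i in range(depth)]
        self.btl = Conv2d(enc_ch[-1], c * 2 ** depth, rng=rng)
        self.dec = []
        for i in reversed(range(depth)):
            cin = c * 2 ** (i + 1) + (c * 2 ** i if use_skips else 0)
            self.dec.append(Conv2d(cin, c * 2 ** i, rng=rng))
        self.final = Conv2d(c, 1, k=1, rng=rng)
        self.head = Dense(c * 2 ** depth, 1, rng=rng) if with_head else None
        self._cache = None

    # -- parameters ---------------------------------------------------------
    def _layers(self) -> dict:
        d = {f"enc{i}": l for i, l in enumerate(self.enc)}
        d["btl"] = self.btl
        d.update({f"dec{i}": l for i, l in enumerate(self.dec)})
        d["final"] = self.final
        if self.head is not None:
            d["head"] = self.head
        return d

    def encoder_params(self) -> list[Param]:
        return [p for l in self.enc for p in l.params()] + self.btl.params()

    def decoder_params(self) -> list[Param]:
        out = [p for l in self.dec for p in l.params()] + self.final.params()
        if self.head is not None:
            out += self.head.params()
        return out

    def params(self) -> list[Param]:
        return self.encoder_params() + self.decoder_params()

    def param_count(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.value.copy() for k, p in _named_params(self._layers()).items()}

    def load_state_dict(self, state: dict) -> None:
        for k, p in _named_params(self._layers()).items():
            p.value = np.asarray(state[k], dtype=DTYPE).copy()

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False):
        """Returns ``(seg_logits (B,H,W), head_logits (B,) or None)``."""
        if x.ndim != 4 or x.shape[3] != self.in_channels:
            raise ValueError(
                f"expected NHWC input with {self.in_channels} channels, "
                f"got shape {x.shape}")
        B, H, W, _ = x.shape
        if H % 2 ** self.depth or W % 2 ** self.depth:
            raise ValueError(
                f"input size {H}x{W} not divisible by {2 ** self.depth}")
        a = x.astype(DTYPE, copy=False)
        enc_caches, skips = [], []
        for conv in self.enc:
            h = conv.forward(a, train=train)
            h, rm = relu(h)
            skips.append(h)
            a, pm = maxpool2(h)
            enc_caches.append((rm, pm))
        h = self.btl.forward(a, train=train)
        bfeat, brm = relu(h)
        head_logits = None
        if self.head is not None:
            pooled = global_avg_pool(bfeat)
            head_logits = self.head.forward(pooled, train=train)[:, 0]
        a = bfeat
        dec_caches = []
        for i, conv in enumerate(self.dec):
            u = upsample2(a)
            if self.use_skips:
                s = skips[self.depth - 1 - i]
                cat = np.concatenate([u, s], axis=3)
            else:
                cat = u
            h = conv.forward(cat, train=train)
            a, rm = relu(h)
            dec_caches.append((rm, u.shape[3]))
        seg_logits = self.final.forward(a, train=train)[..., 0]
        if train:
            self._cache = (enc_caches, dec_caches, brm, bfeat.shape)
        return seg_logits, head_logits

    def backward(self, dseg: np.ndarray, dhead: np.ndarray | None = None) -> None:
        enc_caches, dec_caches, brm, bshape = self._cache
        d = self.final.backward(dseg[..., None].astype(DTYPE, copy=False))
        skip_grads = [None] * self.depth
        for i in reversed(range(len(self.dec))):
            rm, u_ch = dec_caches[i]
            d = relu_backward(d, rm)
            dcat = self.dec[i].backward(d)
            du = dcat[..., :u_ch]
            if self.use_skips:
                skip_grads[self.depth - 1 - i] = dcat[..., u_ch:]
            d = upsample2_backward(du)
        # d now flows into the bottleneck output; add the head branch
        if dhead is not None and self.head is not None:
            dh = self.head.backward(dhead[:, None].astype(DTYPE, copy=False))
            d = d + global_avg_pool_backward(dh, bshape)
        d = relu_backward(d, brm)
        d = self.btl.backward(d)
        for i in reversed(range(self.depth)):
            rm, pm = enc_caches[i]
            d = maxpool2_backward(d, pm)
            if skip_grads[i] is not None:
                d = d + skip_grads[i]
            d = relu_backward(d, rm)
            d = self.enc[i].backward(d)
        self._cache = None
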