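"""Layers with explicit forward/backward passes (channels-last float32)."""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.decay = decay  # whether weight decay applies

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Conv2d:
    """3x3 (or kxk) same-padding convolution via im2col, stride 1."""

    def __init__(self, cin: int, cout: int, k: int = 3, *,
                 rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k * k
        scale = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU stacks
        self.W = Param(rng.normal(0.0, scale, size=(k * k * cin, cout)))
        self.b = Param(np.zeros(cout), decay=False)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, H, W, C = x.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {C}")
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = np.concatenate(
            [xp[:, i:i + H, j:j + W, :] for i in range(k) for j in range(k)],
            axis=3,
        ).reshape(-1, k * k * C)
        out = cols @ self.W.value + self.b.value
        if train:
            self._cache = (cols, (B, H, W, C))
        return out.reshape(B, H, W, self.cout)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (B, H, W, C) = self._cache
        k, p = self.k, self.k // 2
        d2 = dout.reshape(-1, self.cout)
        self.W.grad += cols.T @ d2
        self.b.grad += d2.sum(axis=0)
        dcols = (d2 @ self.W.value.T).reshape(B, H, W, k * k * C)
        dxp = np.zeros((B, H + 2 * p, W + 2 * p, C), dtype=DTYPE)
        idx = 0
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + H, j:j + W, :] += dcols[..., idx * C:(idx + 1) * C]
                idx += 1
        self._cache = None
        return dxp[:, p:p + H, p:p + W, :]


class Dense:
    def __init__(self, fin: int, fout: int, *, rng: np.random.Generator):
        scale = np.sqrt(2.0 / fin)
        self.W = Param(rng.normal(0.0, scale, size=(fin, fout)))
        self.b = Param(np.zeros(fout), decay=False)
        self._x = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        dx = dout @ self.W.value.T
        self._x = None
        return dx


# ----- stateless ops (caller keeps the cache) ------------------------------


def relu(x: np.ndarray):
    out = np.maximum(x, 0.0)
    return out, (x > 0.0)


def relu_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dout * mask


def maxpool2(x: np.ndarray):
    """2x2 max pooling; returns the pooled map and a routing mask."""
    B, H, W, C = x.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2 requires even spatial dimensions")
    win = x.reshape(B, H // 2, 2, W // 2, 2, C)
    out = win.max(axis=(2, 4))
    # distribute gradient equally over tied maxima (deterministic)
    mask = (win == out[:, :, None, :, None, :])
    norm = mask.sum(axis=(2, 4), keepdims=True)
    return out, mask / norm


def maxpool2_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    B, Hh, _, Wh, _, C = mask.shape
    d = dout[:, :, None, :, None, :] * mask
    return d.reshape(B, Hh * 2, Wh * 2, C)


def upsample2(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbour 2x upsampling."""
    return x.repeat(2, axis=1).repeat(2, axis=2)


def upsample2_backward(dout: np.ndarray) -> np.ndarray:
    B, H, W, C = dout.shape
    return dout.reshape(B, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4))


def global_avg_pool(x: np.ndarray) -> np.ndarray:
    return x.mean(axis=(1, 2))


def global_avg_pool_backward(dout: np.ndarray, shape) -> np.ndarray:
    B, H, W, C = shape
    return np.broadcast_to(dout[:, None, None, :] / (H * W), shape).astype(DTYPE)
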