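"""Minimal 3D convolutional network engine in numpy.

Layers operate on single samples shaped ``(channels, x, y, z)`` (the
training protocol uses mini-batches of 1). Convolutions are same-padding
3x3x3 (or 1x1x1) implemented as im2col + BLAS GEMM, chunked along the x
axis to bound peak memory; the data gradient of a stride-1 same-padding
convolution is itself a same-padding convolution with spatially flipped,
channel-transposed kernels, so backprop reuses the same primitive.

Every layer caches what its backward pass needs; ``backward`` consumes the
gradient w.r.t. the layer output and returns the gradient w.r.t. its input
while accumulating parameter gradients in ``.grads``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# Cap on the number of elements materialized per im2col chunk (~256 MB at
# float32). Chosen to keep the full-scale 96x96x48 network inside a few GB.
_CHUNK_ELEMS = 64_000_000


def _conv3d_same(x: np.ndarray, W: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """Stride-1, same-padding 3D correlation: (Ci,X,Y,Z) -> (Co,X,Y,Z)."""
    c_in, X, Y, Z = x.shape
    c_out, _, kx, ky, kz = W.shape
    if (kx, ky, kz) == (1, 1, 1):
        out = np.tensordot(W[:, :, 0, 0, 0], x, axes=(1, 0))
    else:
        pad = ((0, 0), (1, 1), (1, 1), (1, 1))
        xp = np.pad(x, pad)
        Wm = W.reshape(c_out, -1)
        out = np.empty((c_out, X, Y, Z), dtype=x.dtype)
        step = max(1, _CHUNK_ELEMS // max(c_in * 27 * Y * Z, 1))
        for x0 in range(0, X, step):
            x1 = min(X, x0 + step)
            win = sliding_window_view(xp[:, x0 : x1 + 2], (3, 3, 3), axis=(1, 2, 3))
            col = win.transpose(0, 4, 5, 6, 1, 2, 3).reshape(c_in * 27, -1)
            out[:, x0:x1] = (Wm @ col).reshape(c_out, x1 - x0, Y, Z)
    if b is not None:
        out += b.reshape(-1, 1, 1, 1)
    return out


def _conv3d_weight_grad(x: np.ndarray, dy: np.ndarray, ksize: int) -> np.ndarray:
    """Gradient w.r.t. kernels: dW[o,c,k] = sum_p dy[o,p] * x[c, p+k-1]."""
    c_in, X, Y, Z = x.shape
    c_out = dy.shape[0]
    if ksize == 1:
        dW = (dy.reshape(c_out, -1) @ x.reshape(c_in, -1).T).reshape(c_out, c_in, 1, 1, 1)
        return dW
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    dWm = np.zeros((c_out, c_in * 27), dtype=x.dtype)
    step = max(1, _CHUNK_ELEMS // max(c_in * 27 * Y * Z, 1))
    for x0 in range(0, X, step):
        x1 = min(X, x0 + step)
        win = sliding_window_view(xp[:, x0 : x1 + 2], (3, 3, 3), axis=(1, 2, 3))
        col = win.transpose(0, 4, 5, 6, 1, 2, 3).reshape(c_in * 27, -1)
        dWm += dy[:, x0:x1].reshape(c_out, -1) @ col.T
    return dWm.reshape(c_out, c_in, 3, 3, 3)


class Conv3d:
    """Same-padding 3D convolution with He-normal initialization."""

    def __init__(self, c_in: int, c_out: int, ksize: int = 3, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        fan_in = c_in * ksize**3
        self.W = (rng.standard_normal((c_out, c_in, ksize, ksize, ksize)) * np.sqrt(2.0 / fan_in)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.ksize = ksize
        self.grads = {"W": np.zeros_like(self.W), "b": np.zeros_like(self.b)}
        self._x = None

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return _conv3d_same(x, self.W, self.b)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += _conv3d_weight_grad(self._x, dy, self.ksize)
        self.grads["b"] += dy.sum(axis=(1, 2, 3))
        if self.ksize == 1:
            Wt = self.W.transpose(1, 0, 2, 3, 4)
        else:
            Wt = self.W.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
        return _conv3d_same(dy, np.ascontiguousarray(Wt), None)


class ReLU:
    def __init__(self):
        self._mask = None

    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool3d:
    """2x2x2 max pooling with stride 2; spatial dims must be even."""

    def __init__(self):
        self._idx = None
        self._shape = None

    params: dict = {}
    grads: dict = {}

    @staticmethod
    def _blocks(x: np.ndarray) -> np.ndarray:
        c, X, Y, Z = x.shape
        return (
            x.reshape(c, X // 2, 2, Y // 2, 2, Z // 2, 2)
            .transpose(0, 1, 3, 5, 2, 4, 6)
            .reshape(c, X // 2, Y // 2, Z // 2, 8)
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        if any(s % 2 for s in x.shape[1:]):
            raise ValueError(f"max-pool requires even spatial dims, got {x.shape[1:]}")
        blocks = self._blocks(x)
        self._idx = blocks.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(blocks, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, X, Y, Z = self._shape
        blocks = np.zeros((c, X // 2, Y // 2, Z // 2, 8), dtype=dy.dtype)
        np.put_along_axis(blocks, self._idx[..., None], dy[..., None], axis=-1)
        return (
            blocks.reshape(c, X // 2, Y // 2, Z // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(c, X, Y, Z)
        )


class Upsample3d:
    """Nearest-neighbor x2 upsampling."""

    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.repeat(np.repeat(np.repeat(x, 2, axis=1), 2, axis=2), 2, axis=3)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, X, Y, Z = dy.shape
        return dy.reshape(c, X // 2, 2, Y // 2, 2, Z // 2, 2).sum(axis=(2, 4, 6))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def soft_dice_loss(p: np.ndarray, g: np.ndarray, eps: float = 1.0) -> tuple[float, np.ndarray]:
    """Soft Dice loss 1 - (2<p,g>+eps)/(sum p + sum g + eps) and dL/dp."""
    g = g.astype(p.dtype)
    inter = float((p * g).sum())
    denom = float(p.sum() + g.sum()) + eps
    num = 2.0 * inter + eps
    loss = 1.0 - num / denom
    dp = -(2.0 * g * denom - num) / denom**2
    return loss, dp.astype(p.dtype)


def bce_loss(
    p: np.ndarray, g: np.ndarray, eps: float = 1e-7, pos_weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on probabilities and its gradient.

    ``pos_weight`` scales the foreground term, countering the extreme
    class imbalance of small tumors in large volumes.
    """
    g = g.astype(p.dtype)
    pc = np.clip(p, eps, 1.0 - eps)
    n = p.size
    loss = float(-(pos_weight * g * np.log(pc) + (1.0 - g) * np.log(1.0 - pc)).mean())
    dp = (-pos_weight * g / pc + (1.0 - g) / (1.0 - pc)) / n
    return loss, dp.astype(p.dtype)


def dice_bce_loss(p: np.ndarray, g: np.ndarray, max_pos_weight: float = 50.0) -> tuple[float, np.ndarray]:
    """Soft Dice plus foreground-weighted BCE.

    The BCE term keeps foreground logits from saturating at zero (the
    all-background attractor of pure soft Dice under heavy class
    imbalance); the Dice term optimizes the reported overlap metric.
    The foreground weight is the background/foreground voxel ratio,
    capped at ``max_pos_weight``.
    """
    n_fg = float(g.sum())
    w = min(max_pos_weight, (g.size - n_fg) / max(n_fg, 1.0))
    l1, d1 = soft_dice_loss(p, g)
    l2, d2 = bce_loss(p, g, pos_weight=w)
    return l1 + l2, d1 + d2


class Adam:
    """Adam over a list of (layer, param-name) pairs, with optional L2 decay."""

    def __init__(self, layers, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8, weight_decay=0.0):
        self.entries = [(lyr, name) for lyr in layers for name in lyr.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(lyr.params[name]) for lyr, name in self.entries]
        self.v = [np.zeros_like(lyr.params[name]) for lyr, name in self.entries]
        self.t = 0

    def zero_grad(self):
        for lyr, name in self.entries:
            lyr.grads[name][...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (lyr, name) in enumerate(self.entries):
            p = lyr.params[name]
            g = lyr.grads[name]
            if self.weight_decay and name == "W":
                g = g + self.weight_decay * p
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
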