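"""Minimal NumPy neural-network primitives for small 3D volumes.

Internally activations are stored channels-leading, ``(C, B, D, H, W)``:
with that layout im2col and its adjoint reduce to contiguous block copies
per kernel offset and the convolution itself to a single BLAS matmul, which
keeps desk-scale (16³–32³ patch) training fast on one CPU core.  The
network front-end converts from/to the conventional ``(B, C, D, H, W)``.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: stateless unless it owns parameters."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


def _offsets(k: int):
    return [(i, j, l) for i in range(k) for j in range(k) for l in range(k)]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(C, B, D, H, W) -> (C*k^3, B*D*H*W) patch matrix."""
    c, b, d, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    cols = np.empty((c, k**3, b * d * h * w), dtype=np.float32)
    for o, (i, j, l) in enumerate(_offsets(k)):
        cols[:, o] = x[:, :, i : i + d, j : j + h, l : l + w].reshape(c, -1)
    return cols.reshape(c * k**3, -1)


class Conv3d(Layer):
    """3D convolution with 'same' padding (kernel 3) or pointwise (kernel 1).

    Operates on channels-leading activations; the im2col matrix built in the
    forward pass is cached for the backward pass.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = c_in * kernel**3
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        c, b, d, h, w = x.shape
        if self.k == 1:
            self._cols = x.reshape(c, -1)
        else:
            self._cols = _im2col(x, self.k, self.k // 2)
        y = self.W @ self._cols + self.b[:, None]
        return y.reshape(self.c_out, b, d, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, b, d, h, w = self._shape
        k, pad = self.k, self.k // 2
        dy2 = dy.reshape(self.c_out, -1)
        self.db[...] = dy2.sum(axis=1)
        self.dW[...] = dy2 @ self._cols.T
        dcols = self.W.T @ dy2
        self._cols = None
        if k == 1:
            return dcols.reshape(c, b, d, h, w)
        dcols = dcols.reshape(c, k**3, b, d, h, w)
        dxp = np.zeros((c, b, d + 2 * pad, h + 2 * pad, w + 2 * pad), dtype=np.float32)
        for o, (i, j, l) in enumerate(_offsets(k)):
            dxp[:, :, i : i + d, j : j + h, l : l + w] += dcols[:, o]
        return dxp[:, :, pad:-pad, pad:-pad, pad:-pad]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class MaxPool2(Layer):
    """2×2×2 max pooling; spatial dims must be even.  Tied maxima share the
    incoming gradient equally."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, b, d, h, w = x.shape
        xr = x.reshape(c, b, d // 2, 2, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5, 7))
        self._xr_shape = xr.shape
        self._mask = xr == y[:, :, :, None, :, None, :, None]
        self._counts = self._mask.sum(axis=(3, 5, 7), keepdims=True)
        return y.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dyb = dy[:, :, :, None, :, None, :, None] / self._counts
        dxr = np.where(self._mask, dyb, 0.0).astype(np.float32)
        c, b, d2, _, h2, _, w2, _ = self._xr_shape
        return dxr.reshape(c, b, d2 * 2, h2 * 2, w2 * 2)


class Upsample2(Layer):
    """Nearest-neighbour ×2 upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(np.repeat(x, 2, axis=2), 2, axis=3), 2, axis=4)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, b, d, h, w = dy.shape
        return (
            dy.reshape(c, b, d // 2, 2, h // 2, 2, w // 2, 2)
            .sum(axis=(3, 5, 7))
            .astype(np.float32)
        )


def softmax_cross_entropy(
    logits: np.ndarray,
    targets: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Weighted mean voxel-wise cross-entropy.

    ``logits`` is conventional ``(B, C, D, H, W)``; ``targets`` holds
    integer classes shaped ``(B, D, H, W)``.  ``class_weights`` (length C)
    reweights voxels by their true class; the loss is normalised by the
    total voxel weight.  Returns ``(loss, dlogits)``.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    idx = np.indices(targets.shape)
    onehot = np.zeros_like(p)
    onehot[idx[0], targets, idx[1], idx[2], idx[3]] = 1.0
    if class_weights is None:
        w = None
        total = float(targets.size)
    else:
        cw = np.asarray(class_weights, dtype=np.float32)
        w = cw[targets][:, None]  # (B, 1, D, H, W)
        total = float(w.sum())
    eps = 1e-12
    nll = -(onehot * np.log(p + eps))
    loss = float((nll if w is None else nll * w).sum() / total)
    diff = p - onehot
    dlogits = ((diff if w is None else diff * w) / total).astype(np.float32)
    return loss, dlogits


class SGD:
    """SGD with momentum, optional Nesterov, and per-update learning-rate
    decay ``lr_t = lr / (1 + decay * t)`` (Keras-style)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float,
        momentum: float = 0.0,
        decay: float = 0.0,
        nesterov: bool = False,
    ):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.decay = decay
        self.nesterov = nesterov
        self.velocities = [np.zeros_like(p) for p in params]
        self.iterations = 0

    def step(self, grads: list[np.ndarray]) -> None:
        lr = self.lr / (1.0 + self.decay * self.iterations)
        self.iterations += 1
        for p, g, v in zip(self.params, grads, self.velocities):
            v *= self.momentum
            v -= lr * g
            if self.nesterov:
                p += self.momentum * v - lr * g
            else:
                p += v
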