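"""Minimal CNN building blocks with explicit backpropagation (numpy).

All layers operate on float32 arrays of shape ``(N, C, H, W)``.  Convolutions
use im2col with same-padding; the input gradient is computed as a convolution
of the output gradient with the 180°-rotated, in/out-transposed kernels, which
reuses the same im2col machinery.  Each layer caches what its backward pass
needs and accumulates parameter gradients in ``.grads``.
"""

from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Patches of a same-padded (N, C, H, W) array, shape (N·H·W, C·k·k)."""
    if k == 1:
        n, c, h, w = x.shape
        return x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    n, c, h, w = x.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padded k×k convolution (k odd), He-initialized."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.params = [w.astype(np.float32), np.zeros(c_out, np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = _im2col(x, self.k)
        n, _, h, w = x.shape
        y = self._cols @ self.params[0].T + self.params[1]
        return y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, _, h, w = self._shape
        dy_flat = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.grads[0] += dy_flat.T @ self._cols
        self.grads[1] += dy_flat.sum(axis=0)
        # input gradient = same-conv of dy with rotated, transposed kernels
        w_rot = (
            self.params[0]
            .reshape(self.c_out, self.c_in, self.k, self.k)[:, :, ::-1, ::-1]
            .transpose(1, 0, 2, 3)
            .reshape(self.c_in, self.c_out * self.k * self.k)
        )
        cols_dy = _im2col(dy, self.k)
        dx = cols_dy @ w_rot.T
        return dx.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2(Layer):
    """2×2 max pooling; ties resolve to the first maximum."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = (
            x.reshape(n, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h // 2, w // 2, 4)
        )
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        return (
            dxr.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class UpsampleNearest2(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = dy.shape
        return dy.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_with_softmax(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean pixelwise categorical cross-entropy and its gradient w.r.t. logits.

    ``logits``: (N, Nc, H, W); ``labels``: (N, H, W) integer classes.  The loss
    is averaged (not summed) over pixels and batch for learning-rate
    portability; the sum differs only by a constant factor.
    """
    p = softmax(logits, axis=1)
    n, _, h, w = logits.shape
    picked = np.take_along_axis(p, labels[:, None, :, :], axis=1)[:, 0]
    loss = float(-np.log(np.clip(picked, 1e-12, None)).mean())
    grad = p.copy()
    np.put_along_axis(grad, labels[:, None, :, :], (picked - 1.0)[:, None], axis=1)
    grad /= n * h * w
    return loss, grad.astype(logits.dtype, copy=False)
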