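"""Differentiable layers on single ``(C, H, W)`` float32 images.

Each layer caches what its backward pass needs during ``forward`` and exposes
``params`` / ``grads`` dicts for the optimizer.  Convolutions use same
padding and are evaluated as k*k shifted matrix products, which maps the
whole spatial cost onto BLAS.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """k x k convolution, stride 1, same (zero) padding, odd k."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.k = k
        std = np.sqrt(2.0 / (c_in * k * k))  # He init for ReLU nets
        self.params = {
            "W": (rng.standard_normal((c_out, c_in, k, k)) * std).astype(DTYPE),
            "b": np.zeros(c_out, dtype=DTYPE),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._xp = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        W, b = self.params["W"], self.params["b"]
        c_out = W.shape[0]
        _, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p)))
        self._xp = xp
        y = np.empty((c_out, h * w), dtype=DTYPE)
        y[:] = b[:, None]
        for i in range(self.k):
            for j in range(self.k):
                patch = np.ascontiguousarray(xp[:, i : i + h, j : j + w]).reshape(-1, h * w)
                y += W[:, :, i, j] @ patch
        return y.reshape(c_out, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        W = self.params["W"]
        xp = self._xp
        c_out, h, w = dy.shape
        p = self.k // 2
        dyf = dy.reshape(c_out, h * w)
        dxp = np.zeros_like(xp)
        dW = self.grads["W"]
        for i in range(self.k):
            for j in range(self.k):
                patch = np.ascontiguousarray(xp[:, i : i + h, j : j + w]).reshape(-1, h * w)
                dW[:, :, i, j] = dyf @ patch.T
                dxp[:, i : i + h, j : j + w] += (W[:, :, i, j].T @ dyf).reshape(-1, h, w)
        self.grads["b"] = dyf.sum(axis=1)
        return dxp[:, p : p + h, p : p + w]


class ReLU(Layer):
    """Rectifier; a small negative slope keeps units recoverable after
    aggressive early updates (slope 0 is the classic ReLU)."""

    def __init__(self, negative_slope: float = 0.0):
        super().__init__()
        self.negative_slope = DTYPE(negative_slope)
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.negative_slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.negative_slope * dy)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2, ceil mode (odd sizes padded with -inf)."""

    def __init__(self):
        super().__init__()
        self._argmax = None
        self._in_shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        self._in_shape = (c, h, w)
        ho, wo = (h + 1) // 2, (w + 1) // 2
        xp = np.full((c, ho * 2, wo * 2), -np.inf, dtype=x.dtype)
        xp[:, :h, :w] = x
        windows = xp.reshape(c, ho, 2, wo, 2).transpose(0, 1, 3, 2, 4).reshape(c, ho, wo, 4)
        self._argmax = windows.argmax(axis=-1)
        return windows.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, h, w = self._in_shape
        ho, wo = dy.shape[1], dy.shape[2]
        dwin = np.zeros((c, ho, wo, 4), dtype=dy.dtype)
        np.put_along_axis(dwin, self._argmax[..., None], dy[..., None], axis=-1)
        dxp = dwin.reshape(c, ho, wo, 2, 2).transpose(0, 1, 3, 2, 4).reshape(c, ho * 2, wo * 2)
        return dxp[:, :h, :w]


class Upsample2(Layer):
    """Nearest-neighbour x2 upsampling cropped to a target spatial size."""

    def __init__(self):
        super().__init__()
        self._in_hw = None
        self._out_hw = None

    def forward(self, x: np.ndarray, target_hw: tuple[int, int]) -> np.ndarray:
        self._in_hw = x.shape[1:]
        th, tw = target_hw
        if th > 2 * x.shape[1] or tw > 2 * x.shape[2]:
            raise ValueError("x2 upsampling cannot reach target size")
        self._out_hw = (th, tw)
        y = np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)
        return y[:, :th, :tw]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w = self._in_hw
        c = dy.shape[0]
        full = np.zeros((c, 2 * h, 2 * w), dtype=dy.dtype)
        full[:, : self._out_hw[0], : self._out_hw[1]] = dy
        return full.reshape(c, h, 2, w, 2).sum(axis=(2, 4))
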