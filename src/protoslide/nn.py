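"""Minimal differentiable layers and an Adam optimizer, in pure numpy.

The episodic trainer needs a small convolutional encoder it can fit on a
single CPU, together with exact gradients of the prototypical loss; no
deep-learning framework is assumed.  The scope is deliberately narrow:
strided 2-D convolution (im2col + GEMM), ReLU, global average pooling and
a dense projection, composed by :class:`Sequential`.  Gradients are
computed layer by layer in reverse; the test suite checks them against
central finite differences.

Arrays are channels-last ``(B, H, W, C)``.  ``dtype`` is configurable:
float32 for training speed, float64 for gradient checks.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "GlobalAvgPool", "Dense", "Sequential", "Adam"]


class Layer:
    """Forward/backward contract; parameters and gradients as flat lists."""

    def params(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, *, cache: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Return (dx, grads aligned with params())."""
        raise NotImplementedError


class Conv2d(Layer):
    """Strided 2-D convolution with zero padding, channels-last.

    Weights are stored GEMM-ready as ``(kh * kw * c_in, c_out)``; He-normal
    initialization scaled by fan-in.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        *,
        rng: np.random.Generator,
        dtype: np.dtype = np.float32,
        compute_dx: bool = True,
    ):
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.pad = kernel, stride, pad
        # the first layer of a network never needs d loss / d input
        self.compute_dx = compute_dx
        fan_in = kernel * kernel * c_in
        self.W = (rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self._cache: tuple | None = None

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        b, h, w, c = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        hp, wp = x.shape[1], x.shape[2]
        ho = (hp - k) // s + 1
        wo = (wp - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
        win = win[:, ::s, ::s]  # (b, ho, wo, c, k, k)
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(b * ho * wo, k * k * c)
        return np.ascontiguousarray(cols), (b, ho, wo, hp, wp)

    def forward(self, x: np.ndarray, *, cache: bool) -> np.ndarray:
        cols, (b, ho, wo, hp, wp) = self._im2col(x)
        y = cols @ self.W + self.b
        if cache:
            self._cache = (cols, x.shape, (b, ho, wo, hp, wp))
        return y.reshape(b, ho, wo, self.c_out)

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        if self._cache is None:
            raise RuntimeError("forward(cache=True) must run before backward")
        cols, x_shape, (b, ho, wo, hp, wp) = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        dy_flat = np.ascontiguousarray(dy.reshape(b * ho * wo, self.c_out))
        dW = cols.T @ dy_flat
        db = dy_flat.sum(axis=0)
        if not self.compute_dx:
            return np.zeros(x_shape, dtype=dy.dtype), [dW, db]
        dcols = (dy_flat @ self.W.T).reshape(b, ho, wo, k, k, self.c_in)
        dx_pad = np.zeros((b, hp, wp, self.c_in), dtype=dy.dtype)
        # scatter the column gradients back; k*k strided adds instead of add.at
        for i in range(k):
            for j in range(k):
                dx_pad[:, i : i + s * ho : s, j : j + s * wo : s, :] += dcols[:, :, :, i, j, :]
        dx = dx_pad[:, p : hp - p, p : wp - p, :] if p else dx_pad
        return dx, [dW, db]


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, *, cache: bool) -> np.ndarray:
        y = np.maximum(x, 0)
        if cache:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        if self._mask is None:
            raise RuntimeError("forward(cache=True) must run before backward")
        return dy * self._mask, []


class GlobalAvgPool(Layer):
    """Mean over the spatial axes: (B, H, W, C) -> (B, C)."""

    def __init__(self) -> None:
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, *, cache: bool) -> np.ndarray:
        if cache:
            self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        if self._shape is None:
            raise RuntimeError("forward(cache=True) must run before backward")
        b, h, w, c = self._shape
        dx = np.broadcast_to(dy[:, None, None, :] / (h * w), (b, h, w, c)).astype(dy.dtype)
        return dx, []


class Dense(Layer):
    def __init__(
        self, d_in: int, d_out: int, *, rng: np.random.Generator, dtype: np.dtype = np.float32
    ):
        self.W = (rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)).astype(dtype)
        self.b = np.zeros(d_out, dtype=dtype)
        self._x: np.ndarray | None = None

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, *, cache: bool) -> np.ndarray:
        if cache:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        if self._x is None:
            raise RuntimeError("forward(cache=True) must run before backward")
        return dy @ self.W.T, [self._x.T @ dy, dy.sum(axis=0)]


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def set_params(self, values: list[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(values):
            raise ValueError("parameter count mismatch")
        for dst, src in zip(own, values):
            if dst.shape != src.shape:
                raise ValueError(f"shape mismatch {dst.shape} vs {src.shape}")
            dst[...] = src

    def forward(self, x: np.ndarray, *, cache: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, cache=cache)
        return x

    def backward(self, dy: np.ndarray) -> list[np.ndarray]:
        """Gradients for every parameter, aligned with :meth:`params`."""
        grads_rev: list[np.ndarray] = []
        for layer in reversed(self.layers):
            dy, layer_grads = layer.backward(dy)
            grads_rev.extend(reversed(layer_grads))
        return list(reversed(grads_rev))


class Adam:
    """Adam with the usual bias correction; ``lr`` may be changed per epoch."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        if len(grads) != len(self.params):
            raise ValueError("gradient count mismatch")
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
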