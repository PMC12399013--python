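"""Minimal NumPy neural-network engine.

Implements exactly the layer vocabulary the GallNet architecture needs:
same-padded 2-D cross-correlation (im2col + GEMM), batch normalization,
2x2 max-pooling, dense layers, dropout, ReLU and softmax, together with
hand-written backward passes and an Adam optimizer.  Tensors are NHWC
(batch, height, width, channels); dtype follows the layer parameters
(float32 for training speed, float64 available for high-precision
gradient checks).

The forward passes cache whatever the backward passes need when
``cache`` is requested (it defaults to the value of ``training``);
explanation code runs inference-mode forward passes with caching on so
gradients can be taken without switching batch-norm to batch statistics.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "BatchNorm",
    "ReLU",
    "MaxPool2x2",
    "Flatten",
    "Dense",
    "Dropout",
    "softmax",
    "Adam",
]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shift-invariant softmax: exp(z - max z) / sum exp(z - max z)."""
    z = np.asarray(z, dtype=float)
    shifted = z - z.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Extract k x k patches of a same-padded NHWC tensor.

    Returns an array of shape (N, H, W, k*k*C) whose last axis is the
    flattened receptive field at each output position.
    """
    n, h, w, c = x.shape
    p = k // 2
    if p:
        x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    # sliding_window_view gives (N, H, W, C, k, k); put the window axes
    # before C so the flattened ordering matches the kernel layout below.
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    win = win.transpose(0, 1, 2, 4, 5, 3)  # (N, H, W, k, k, C)
    return np.ascontiguousarray(win).reshape(n, h, w, k * k * c)


class Layer:
    """Base layer interface."""

    name = "layer"

    def forward(self, x: np.ndarray, training: bool = False,
                cache: bool | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def state(self) -> dict[str, np.ndarray]:
        """Non-trainable buffers (e.g. BN running statistics)."""
        return {}


class Conv2D(Layer):
    """Same-padded 2-D cross-correlation with bias.

    Kernel layout is (k, k, C_in, F), matching the convolution
    definition used throughout the package: the output at (i, j) is the
    inner product of the kernel with the input patch whose top-left
    corner is (i, j) in padded coordinates (no kernel flip).

    Two mathematically identical execution strategies are used depending
    on the layer geometry: an im2col + single GEMM (best when the
    receptive field is small, e.g. few input channels) and a
    shift-and-accumulate scheme doing one GEMM per kernel offset (best at
    large spatial extents, where materializing the k*k*C patch matrix is
    memory-bound).  1x1 kernels collapse to a plain GEMM.
    """

    def __init__(self, c_in: int, filters: int, kernel_size: int, name: str,
                 rng: np.random.Generator, dtype=np.float32):
        if kernel_size % 2 != 1 or kernel_size < 1:
            raise ValueError("kernel_size must be an odd positive integer")
        self.k = kernel_size
        self.c_in = c_in
        self.filters = filters
        self.name = name
        fan_in = kernel_size * kernel_size * c_in
        limit = np.sqrt(6.0 / fan_in)  # variance-scaling fan-in uniform
        self.w = rng.uniform(-limit, limit,
                             size=(kernel_size, kernel_size, c_in, filters)).astype(dtype)
        self.b = np.zeros(filters, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache: np.ndarray | None = None

    def _use_shift(self, h: int, w: int) -> bool:
        # shift-and-accumulate pays off when the patch matrix would be
        # large and each per-offset GEMM still has a decent inner dim
        return self.k > 1 and self.c_in >= 8 and h * w >= 1024

    def forward(self, x, training=False, cache=None):
        if x.shape[-1] != self.c_in:
            raise ValueError(
                f"{self.name}: expected {self.c_in} input channels, got {x.shape[-1]}")
        n, h, w, _ = x.shape
        x = x.astype(self.w.dtype, copy=False)
        keep = training if cache is None else cache
        k, f, c = self.k, self.filters, self.c_in
        if k == 1:
            flat = x.reshape(n * h * w, c)
            out = flat @ self.w.reshape(c, f) + self.b
            if keep:
                self._cache = ("flat", flat, (n, h, w))
        elif self._use_shift(h, w):
            p = k // 2
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
            out = np.zeros((n * h * w, f), dtype=x.dtype)
            for u in range(k):
                for v in range(k):
                    xs = np.ascontiguousarray(
                        xp[:, u:u + h, v:v + w, :]).reshape(n * h * w, c)
                    out += xs @ self.w[u, v]
            out += self.b
            if keep:
                self._cache = ("pad", xp, (n, h, w))
        else:
            cols = _im2col(x, k).reshape(n * h * w, k * k * c)
            out = cols @ self.w.reshape(-1, f) + self.b
            if keep:
                self._cache = ("cols", cols, (n, h, w))
        return out.reshape(n, h, w, f)

    def backward(self, dout):
        n, h, w, f = dout.shape
        kind, cached, _ = self._cache
        k, c = self.k, self.c_in
        p = k // 2
        dflat = dout.reshape(n * h * w, f)
        self.db[...] = dflat.sum(axis=0)
        if kind == "flat":
            self.dw[...] = (cached.T @ dflat).reshape(self.w.shape)
            dx = (dflat @ self.w.reshape(c, f).T).reshape(n, h, w, c)
        elif kind == "pad":
            xp = cached
            dxp = np.zeros_like(xp)
            for u in range(k):
                for v in range(k):
                    xs = np.ascontiguousarray(
                        xp[:, u:u + h, v:v + w, :]).reshape(n * h * w, c)
                    self.dw[u, v] = xs.T @ dflat
                    dxp[:, u:u + h, v:v + w, :] += (
                        dflat @ self.w[u, v].T).reshape(n, h, w, c)
            dx = dxp[:, p:-p, p:-p, :]
        else:
            cols = cached
            self.dw[...] = (cols.T @ dflat).reshape(self.w.shape)
            # adjoint of im2col: scatter each output position's
            # contribution back over its receptive field
            dcols = (dflat @ self.w.reshape(-1, f).T).reshape(n, h, w, k, k, c)
            dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=dout.dtype)
            for u in range(k):
                for v in range(k):
                    dxp[:, u:u + h, v:v + w, :] += dcols[:, :, :, u, v, :]
            dx = dxp[:, p:-p, p:-p, :] if p else dxp
        self._cache = None
        return dx

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W) with trainable
    scale/shift and exponential running statistics for inference.

    The backward pass covers both modes: after a training-mode forward it
    uses the full batch-statistics Jacobian; after an inference-mode
    forward (running statistics are constants) it is the affine map
    dx = dout * gamma / sqrt(running_var + eps), which is what gradient-
    based explainers need.
    """

    def __init__(self, channels: int, name: str, eps: float = 1e-5,
                 momentum: float = 0.8, dtype=np.float32):
        self.name = name
        self.eps = eps
        self.momentum = momentum
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._mode: str | None = None

    def forward(self, x, training=False, cache=None):
        axes = tuple(range(x.ndim - 1))
        keep = training if cache is None else cache
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv
            if keep:
                self._mode = "train"
                self._xhat = xhat
                self._inv = inv.astype(x.dtype)
                self._axes = axes
                self._count = x.size // x.shape[-1]
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * inv
            if keep:
                self._mode = "eval"
                self._xhat = xhat
                self._inv = inv.astype(x.dtype)
                self._axes = axes
        return (self.gamma * xhat + self.beta).astype(x.dtype, copy=False)

    def backward(self, dout):
        xhat, inv, axes = self._xhat, self._inv, self._axes
        self.dgamma[...] = (dout * xhat).sum(axis=axes)
        self.dbeta[...] = dout.sum(axis=axes)
        if self._mode == "eval":
            dx = dout * (self.gamma * inv)
        else:
            m = self._count
            dxhat = dout * self.gamma
            dx = (inv / m) * (m * dxhat
                              - dxhat.sum(axis=axes)
                              - xhat * (dxhat * xhat).sum(axis=axes))
        self._xhat = None
        self._mode = None
        return dx.astype(dout.dtype, copy=False)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        self.name = name

    def forward(self, x, training=False, cache=None):
        out = np.maximum(x, 0)
        if training if cache is None else cache:
            self._mask = x > 0
        return out

    def backward(self, dout):
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2x2(Layer):
    """2x2 max-pool, stride 2.  Odd spatial extents are an error."""

    def __init__(self, name: str = "pool"):
        self.name = name

    def forward(self, x, training=False, cache=None):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(
                f"{self.name}: 2x2 pooling requires even spatial extents, got {h}x{w}")
        windows = x.reshape(n, h // 2, 2, w // 2, 2, c)
        flat = np.ascontiguousarray(
            windows.transpose(0, 1, 3, 5, 2, 4)).reshape(n, h // 2, w // 2, c, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if training if cache is None else cache:
            self._idx = idx
            self._in_shape = x.shape
        return out

    def backward(self, dout):
        n, h, w, c = self._in_shape
        dflat = np.zeros((n, h // 2, w // 2, c, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, self._idx[..., None], dout[..., None], axis=-1)
        dx = dflat.reshape(n, h // 2, w // 2, c, 2, 2)
        dx = dx.transpose(0, 1, 4, 2, 5, 3).reshape(n, h, w, c)
        self._idx = None
        return dx


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        self.name = name

    def forward(self, x, training=False, cache=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer; ``l2`` is the coefficient of the penalty
    l2 * sum(w**2) added to the training loss (bias excluded)."""

    def __init__(self, n_in: int, n_out: int, name: str,
                 rng: np.random.Generator, l2: float = 0.0, dtype=np.float32):
        self.name = name
        limit = np.sqrt(6.0 / n_in)
        self.w = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.l2 = l2

    def forward(self, x, training=False, cache=None):
        if training if cache is None else cache:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw[...] = self._x.T @ dout
        if self.l2:
            self.dw += (2.0 * self.l2) * self.w
        self.db[...] = dout.sum(axis=0)
        dx = dout @ self.w.T
        self._x = None
        return dx

    def l2_penalty(self) -> float:
        return float(self.l2 * np.sum(self.w.astype(np.float64) ** 2))

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}


class Dropout(Layer):
    """Inverted dropout: active only in training mode, identity otherwise.

    Draws its masks from a generator handed in by the training loop so a
    run is reproducible end-to-end from a single seed.
    """

    def __init__(self, rate: float, name: str = "dropout"):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.name = name
        self.rng: np.random.Generator | None = None
        self._mask: np.ndarray | None = None

    def forward(self, x, training=False, cache=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError(f"{self.name}: no RNG attached for training mode")
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        self._mask = mask
        return x * mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        dx = dout * self._mask
        self._mask = None
        return dx


class Adam:
    """Adam optimizer over a flat list of (param, grad) array pairs."""

    def __init__(self, params_grads: list[tuple[np.ndarray, np.ndarray]],
                 lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7):
        self.pairs = params_grads
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params_grads]
        self.v = [np.zeros_like(p) for p, _ in params_grads]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for (p, g), m, v in zip(self.pairs, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(p.dtype)
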