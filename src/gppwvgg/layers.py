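"""Minimal CNN layer engine on NumPy.

Every layer implements ``forward`` / ``backward`` with explicit caching, so a
whole model is trainable on a CPU without any deep-learning framework.
Convolutions are stride-1 with "same" zero padding (the only geometry the
VGG-style stacks here need); spatial downsampling is done by 2x2 max pooling.

Shapes follow the (batch, channels, height, width) convention throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class ShapeError(ValueError):
    """Input tensor shape violates a layer's contract."""


class ConfigError(ValueError):
    """Layer / architecture configuration is invalid."""


class Parameter:
    """A learnable array plus its accumulated gradient."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = data
        self.grad = np.zeros_like(data)

    @property
    def size(self) -> int:
        return int(self.data.size)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Parameter({self.name}, shape={self.data.shape})"


class Layer:
    """Base class: children + parameters registry, train/eval mode."""

    def __init__(self):
        self.training = True
        self._params: list[Parameter] = []
        self._children: list[tuple[str, "Layer"]] = []

    # -- registry ---------------------------------------------------------
    def add_param(self, name: str, data: np.ndarray) -> Parameter:
        p = Parameter(name, data)
        self._params.append(p)
        return p

    def add_child(self, name: str, layer: "Layer") -> "Layer":
        self._children.append((name, layer))
        return layer

    def named_parameters(self, prefix: str = ""):
        for p in self._params:
            yield (prefix + p.name if not prefix else f"{prefix}.{p.name}"), p
        for name, child in self._children:
            sub = name if not prefix else f"{prefix}.{name}"
            yield from child.named_parameters(sub)

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children:
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # -- compute ----------------------------------------------------------
    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)

    def out_shape(self, in_shape: tuple) -> tuple:
        """Static (C, H, W) -> (C, H, W) shape map, no batch axis."""
        raise NotImplementedError


# ---------------------------------------------------------------------------
# im2col helpers (stride 1, same padding)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(n, c, h, w) -> (n, c*k*k, h*w) patch matrix for a k x k window."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    v = sliding_window_view(xp, (k, k), axis=(2, 3))  # (n, c, h, w, k, k)
    cols = v.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, h * w)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, n: int, c: int, h: int, w: int, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to an image."""
    p = k // 2
    dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dcols.dtype)
    dv = dcols.reshape(n, c, k, k, h * w).reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += dv[:, :, i, j]
    return dxp[:, :, p : p + h, p : p + w]


# ---------------------------------------------------------------------------
# Core layers
# ---------------------------------------------------------------------------

class Conv2d(Layer):
    """Stride-1, same-padding 2-D convolution (cross-correlation) with groups."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        if kernel_size % 2 != 1 or kernel_size < 1:
            raise ConfigError(f"kernel size must be a positive odd int, got {kernel_size}")
        if in_channels % groups or out_channels % groups:
            raise ConfigError("in/out channels must be divisible by groups")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.groups = groups
        rng = rng or np.random.default_rng(0)
        cg = in_channels // groups
        fan_in = cg * kernel_size * kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels, cg, kernel_size, kernel_size))
        self.weight = self.add_param("weight", w.astype(dtype))
        self.bias = self.add_param("bias", np.zeros(out_channels, dtype=dtype)) if bias else None
        self._cache = None

    def forward(self, x):
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ShapeError(f"expected {self.in_channels} channels, got {c}")
        k, g = self.kernel_size, self.groups
        cg = self.in_channels // g
        og = self.out_channels // g
        y = np.empty((n, self.out_channels, h * w), dtype=x.dtype)
        cols_cache = []
        for gi in range(g):
            xg = x[:, gi * cg : (gi + 1) * cg]
            cols = _im2col(xg, k)                       # (n, cg*k*k, hw)
            wm = self.weight.data[gi * og : (gi + 1) * og].reshape(og, -1)
            y[:, gi * og : (gi + 1) * og] = wm @ cols   # (n, og, hw)
            if self.training:
                cols_cache.append(cols)
        if self.bias is not None:
            y += self.bias.data[None, :, None]
        if self.training:
            self._cache = (cols_cache, x.shape, x.dtype)
        return y.reshape(n, self.out_channels, h, w)

    def backward(self, dy):
        cols_cache, x_shape, dtype = self._cache
        n, c, h, w = x_shape
        k, g = self.kernel_size, self.groups
        cg, og = c // g, self.out_channels // g
        dy_m = dy.reshape(n, self.out_channels, h * w)
        if self.bias is not None:
            self.bias.grad += dy_m.sum(axis=(0, 2))
        dx = np.empty(x_shape, dtype=dtype)
        for gi in range(g):
            dyg = dy_m[:, gi * og : (gi + 1) * og]
            cols = cols_cache[gi]
            dwm = np.einsum("noh,nch->oc", dyg, cols, optimize=True)
            self.weight.grad[gi * og : (gi + 1) * og] += dwm.reshape(og, cg, k, k)
            wm = self.weight.data[gi * og : (gi + 1) * og].reshape(og, -1)
            dcols = np.einsum("oc,noh->nch", wm, dyg, optimize=True)
            dx[:, gi * cg : (gi + 1) * cg] = _col2im(dcols, n, cg, h, w, k)
        return dx

    def out_shape(self, in_shape):
        c, h, w = in_shape
        if c != self.in_channels:
            raise ShapeError(f"expected {self.in_channels} channels, got {c}")
        return (self.out_channels, h, w)


class BatchNorm2d(Layer):
    """Per-channel batch normalisation with learnable affine pair."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.gamma = self.add_param("weight", np.ones(num_features, dtype=dtype))
        self.beta = self.add_param("bias", np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)
        self._cache = None

    def forward(self, x):
        if x.shape[1] != self.num_features:
            raise ShapeError(f"expected {self.num_features} channels, got {x.shape[1]}")
        if self.training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(x.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(x.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        y = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        if self.training:
            self._cache = (xhat, inv)
        return y

    def backward(self, dy):
        xhat, inv = self._cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        dxhat = dy * g
        mean_d = dxhat.sum(axis=(0, 2, 3)) / m
        mean_dx = (dxhat * xhat).sum(axis=(0, 2, 3)) / m
        dx = inv[None, :, None, None] * (
            dxhat - mean_d[None, :, None, None] - xhat * mean_dx[None, :, None, None]
        )
        return dx

    def out_shape(self, in_shape):
        return in_shape


class ReLU(Layer):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x):
        if self.training:
            self._mask = x > 0
            return np.where(self._mask, x, 0)
        return np.maximum(x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)

    def out_shape(self, in_shape):
        return in_shape


class MaxPool2d(Layer):
    """2x2, stride-2 max pooling; ties resolved toward the first element."""

    def __init__(self):
        super().__init__()
        self._cache = None

    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ShapeError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if self.training:
            self._cache = (idx, (n, c, h, w))
        return y

    def backward(self, dy):
        idx, (n, c, h, w) = self._cache
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(n, c, h, w)

    def out_shape(self, in_shape):
        c, h, w = in_shape
        return (c, h // 2, w // 2)


class GlobalAvgPool2d(Layer):
    """(n, c, h, w) -> (n, c) spatial mean."""

    def __init__(self):
        super().__init__()
        self._hw = None

    def forward(self, x):
        if x.shape[2] == 0 or x.shape[3] == 0:
            raise ShapeError("cannot average over an empty spatial grid")
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        h, w = self._hw
        return np.broadcast_to(dy[:, :, None, None], dy.shape + (h, w)).copy() / (h * w)

    def out_shape(self, in_shape):
        return (in_shape[0],)


class Flatten(Layer):
    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(out_features, in_features))
        self.weight = self.add_param("weight", w.astype(dtype))
        self.bias = self.add_param("bias", np.zeros(out_features, dtype=dtype)) if bias else None
        self._x = None

    def forward(self, x):
        if x.shape[1] != self.in_features:
            raise ShapeError(f"expected {self.in_features} features, got {x.shape[1]}")
        if self.training:
            self._x = x
        y = x @ self.weight.data.T
        if self.bias is not None:
            y += self.bias.data
        return y

    def backward(self, dy):
        self.weight.grad += dy.T @ self._x
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.data

    def out_shape(self, in_shape):
        return (self.out_features,)


class Dropout(Layer):
    def __init__(self, p: float = 0.5, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ConfigError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x):
        if not self.training or self.p == 0.0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask

    def out_shape(self, in_shape):
        return in_shape


class Sequential(Layer):
    def __init__(self, layers: list[tuple[str, Layer]] | None = None):
        super().__init__()
        self.layers: list[tuple[str, Layer]] = []
        for name, layer in layers or []:
            self.append(name, layer)

    def append(self, name: str, layer: Layer):
        self.layers.append((name, layer))
        self.add_child(name, layer)
        return layer

    def forward(self, x):
        for _, layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for _, layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def out_shape(self, in_shape):
        for _, layer in self.layers:
            in_shape = layer.out_shape(in_shape)
        return in_shape

    def __iter__(self):
        return iter(self.layers)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CrossEntropyLoss:
    """Softmax cross entropy over integer class targets, mean-reduced."""

    def __init__(self):
        self._probs = None
        self._targets = None

    def forward(self, logits: np.ndarray, targets: np.ndarray) -> float:
        if logits.shape[0] != targets.shape[0]:
            raise ShapeError("logits/targets batch mismatch")
        p = softmax(logits.astype(np.float64))
        self._probs, self._targets = p, targets
        self._dtype = logits.dtype
        n = logits.shape[0]
        return float(-np.log(np.clip(p[np.arange(n), targets], 1e-12, None)).mean())

    def backward(self) -> np.ndarray:
        p, t = self._probs, self._targets
        n = p.shape[0]
        g = p.copy()
        g[np.arange(n), t] -= 1.0
        return (g / n).astype(self._dtype)

    __call__ = forward
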