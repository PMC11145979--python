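"""Building-block operators of the lightweight model family.

Four operators, each a composable :class:`~gppwvgg.layers.Layer`:

* :class:`PartialConv2d` — partial convolution (PConv): a k x k convolution
  over only the first ``cp = floor(r * C)`` channels, untouched channels
  concatenated back, then a 1x1 pointwise mix over all channels.  Convolving
  a channel subset attacks inter-channel feature redundancy at a fraction of
  the dense cost.
* :class:`PartialMixedConv2d` — partially mixed convolution (PMConv): the
  convolved subset is partitioned into contiguous groups, each group given a
  different odd kernel size (MixConv-style mixed receptive fields), then the
  same concatenate-and-pointwise-mix.
* :class:`EfficientChannelAttention` — ECA: global average pool per channel,
  a k-wide 1-D convolution across the channel axis (no dimensionality
  reduction), sigmoid gate.  The kernel width adapts to the channel count
  via :func:`eca_kernel_size`.
* :class:`PointwiseHead` — the FL2PW classifier head: two 1x1 convolutions
  (C -> hidden -> num_classes) and a global average pool, replacing VGG's
  fully connected stack.

Functional wrappers (``partial_conv`` etc.) build a freshly initialised,
seeded operator and apply it once; they exist for quick experimentation,
while the architecture builder composes the layer classes directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .layers import (BatchNorm2d, ConfigError, Conv2d, GlobalAvgPool2d,
                     Layer, ReLU, ShapeError)

DEFAULT_PARTIAL_RATIO = 0.25       # FasterNet's convention for PConv/PMConv
DEFAULT_KERNEL_SET = (3, 5, 7)     # mixed receptive fields for PMConv


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PConvSpec:
    """Partial-convolution geometry: convolve the first ``cp`` channels only."""

    in_channels: int
    out_channels: int
    partial_ratio: float = DEFAULT_PARTIAL_RATIO
    kernel: int = 3

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ConfigError("channel counts must be positive")
        if not 0 < self.partial_ratio <= 1:
            raise ConfigError(f"partial ratio must be in (0, 1], got {self.partial_ratio}")
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ConfigError(f"kernel must be odd and positive, got {self.kernel}")
        if self.cp < 1:
            raise ConfigError(
                f"partial ratio {self.partial_ratio} leaves no channels to "
                f"convolve out of {self.in_channels}")

    @property
    def cp(self) -> int:
        """Width of the convolved channel subset."""
        return math.floor(self.partial_ratio * self.in_channels)


def split_groups(cp: int, n_groups: int) -> list[int]:
    """Near-equal contiguous group sizes; the remainder goes to the last groups.

    E.g. ``split_groups(64, 3) == [21, 21, 22]`` and
    ``split_groups(32, 3) == [10, 11, 11]``.
    """
    base, rem = divmod(cp, n_groups)
    return [base + (1 if i >= n_groups - rem else 0) for i in range(n_groups)]


@dataclass(frozen=True)
class PMConvSpec:
    """Mixed-kernel partial convolution: the ``cp`` subset split across kernels."""

    in_channels: int
    out_channels: int
    partial_ratio: float = DEFAULT_PARTIAL_RATIO
    kernel_set: tuple[int, ...] = DEFAULT_KERNEL_SET
    group_plan: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ConfigError("channel counts must be positive")
        if not 0 < self.partial_ratio <= 1:
            raise ConfigError(f"partial ratio must be in (0, 1], got {self.partial_ratio}")
        if not self.kernel_set:
            raise ConfigError("kernel set must be non-empty")
        if len(set(self.kernel_set)) != len(self.kernel_set):
            raise ConfigError(f"kernel sizes must be distinct, got {self.kernel_set}")
        for k in self.kernel_set:
            if k < 1 or k % 2 == 0:
                raise ConfigError(f"kernel sizes must be odd and positive, got {k}")
        if self.cp < len(self.kernel_set):
            raise ConfigError(
                f"subset width {self.cp} cannot host {len(self.kernel_set)} kernel groups")
        if self.group_plan is not None:
            if len(self.group_plan) != len(self.kernel_set):
                raise ConfigError("group plan and kernel set lengths differ")
            if sum(self.group_plan) != self.cp:
                raise ConfigError(
                    f"group sizes {self.group_plan} must sum to the subset width {self.cp}")
            if any(s < 1 for s in self.group_plan):
                raise ConfigError("group sizes must be positive")

    @property
    def cp(self) -> int:
        return math.floor(self.partial_ratio * self.in_channels)

    @property
    def groups(self) -> list[int]:
        if self.group_plan is not None:
            return list(self.group_plan)
        return split_groups(self.cp, len(self.kernel_set))

    @property
    def kernels_ascending(self) -> list[int]:
        return sorted(self.kernel_set)


@dataclass(frozen=True)
class EcaConfig:
    """ECA geometry: 1-D kernel width adapted to the channel count (gamma, b)."""

    channels: int
    gamma: int = 2
    b: int = 1
    k_min: int = 3

    def __post_init__(self):
        if self.channels < 1:
            raise ConfigError("channel count must be positive")
        if self.gamma < 1:
            raise ConfigError("gamma must be a positive int")
        if self.k_min < 1 or self.k_min % 2 == 0:
            raise ConfigError("k_min must be a positive odd int")

    @property
    def kernel_size(self) -> int:
        return eca_kernel_size(self.channels, self.gamma, self.b, self.k_min)


@dataclass(frozen=True)
class HeadSpec:
    """FL2PW head: PW(in -> hidden) + PW(hidden -> classes) + global avg pool."""

    in_channels: int = 256
    hidden_width: int = 1024
    num_classes: int = 6
    bias: bool = True
    use_bn: bool = True

    def __post_init__(self):
        if min(self.in_channels, self.hidden_width, self.num_classes) < 1:
            raise ConfigError("head widths must be positive")


# ---------------------------------------------------------------------------
# ECA kernel rule
# ---------------------------------------------------------------------------

def eca_kernel_size(channels: int, gamma: int = 2, b: int = 1, k_min: int = 3) -> int:
    """Adaptive odd 1-D kernel width for ECA.

    ``t = floor(|log2(C) + b| / gamma)``; ``t`` is bumped to the next odd
    integer when even, then clamped below by ``k_min`` (the raw rule yields a
    degenerate width 1 for small channel counts).
    """
    if channels < 1:
        raise ConfigError(f"channel count must be positive, got {channels}")
    t = math.floor(abs(math.log2(channels) + b) / gamma)
    k = t if t % 2 == 1 else t + 1
    return max(k, k_min)


# ---------------------------------------------------------------------------
# Operator layers
# ---------------------------------------------------------------------------

class PartialConv2d(Layer):
    """PConv block: partial k x k conv -> concat -> 1x1 mix (-> BN) -> ReLU.

    The k x k stage is bias-free; ``pw_bias`` / ``use_bn`` control the affine
    bookkeeping of the pointwise mix (the lightweight presets run bias-free
    with BN, which is what reproduces the published parameter budgets).
    """

    def __init__(self, spec: PConvSpec, use_bn: bool = True, pw_bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.spec = spec
        rng = rng or np.random.default_rng(0)
        self.conv_p = self.add_child(
            "partial", Conv2d(spec.cp, spec.cp, spec.kernel, bias=False, rng=rng, dtype=dtype))
        self.pw = self.add_child(
            "pw", Conv2d(spec.in_channels, spec.out_channels, 1, bias=pw_bias,
                         rng=rng, dtype=dtype))
        self.bn = self.add_child("bn", BatchNorm2d(spec.out_channels, dtype=dtype)) \
            if use_bn else None
        self.act = self.add_child("act", ReLU())

    def forward(self, x):
        if x.shape[1] != self.spec.in_channels:
            raise ShapeError(
                f"expected {self.spec.in_channels} channels, got {x.shape[1]}")
        cp = self.spec.cp
        y1 = self.conv_p.forward(x[:, :cp])
        z = np.concatenate([y1, x[:, cp:]], axis=1)
        y = self.pw.forward(z)
        if self.bn is not None:
            y = self.bn.forward(y)
        return self.act.forward(y)

    def backward(self, dy):
        dy = self.act.backward(dy)
        if self.bn is not None:
            dy = self.bn.backward(dy)
        dz = self.pw.backward(dy)
        cp = self.spec.cp
        dx = dz.copy()
        dx[:, :cp] = self.conv_p.backward(np.ascontiguousarray(dz[:, :cp]))
        return dx

    def out_shape(self, in_shape):
        c, h, w = in_shape
        if c != self.spec.in_channels:
            raise ShapeError(f"expected {self.spec.in_channels} channels, got {c}")
        return (self.spec.out_channels, h, w)


class PartialMixedConv2d(Layer):
    """PMConv block: the ``cp`` subset split into per-kernel dense groups.

    Group ``i`` (width ``cp_i``) is convolved within-group with kernel
    ``k_i`` (ascending kernel order over contiguous near-equal groups), the
    results are concatenated with the untouched channels and mixed by a 1x1
    convolution, as in :class:`PartialConv2d`.
    """

    def __init__(self, spec: PMConvSpec, use_bn: bool = True, pw_bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.spec = spec
        rng = rng or np.random.default_rng(0)
        self.group_convs: list[Conv2d] = []
        for i, (size, k) in enumerate(zip(spec.groups, spec.kernels_ascending)):
            conv = Conv2d(size, size, k, bias=False, rng=rng, dtype=dtype)
            self.group_convs.append(self.add_child(f"group{i}", conv))
        self.pw = self.add_child(
            "pw", Conv2d(spec.in_channels, spec.out_channels, 1, bias=pw_bias,
                         rng=rng, dtype=dtype))
        self.bn = self.add_child("bn", BatchNorm2d(spec.out_channels, dtype=dtype)) \
            if use_bn else None
        self.act = self.add_child("act", ReLU())

    def forward(self, x):
        if x.shape[1] != self.spec.in_channels:
            raise ShapeError(
                f"expected {self.spec.in_channels} channels, got {x.shape[1]}")
        parts = []
        start = 0
        for conv, size in zip(self.group_convs, self.spec.groups):
            parts.append(conv.forward(np.ascontiguousarray(x[:, start:start + size])))
            start += size
        parts.append(x[:, start:])
        z = np.concatenate(parts, axis=1)
        y = self.pw.forward(z)
        if self.bn is not None:
            y = self.bn.forward(y)
        return self.act.forward(y)

    def backward(self, dy):
        dy = self.act.backward(dy)
        if self.bn is not None:
            dy = self.bn.backward(dy)
        dz = self.pw.backward(dy)
        dx = dz.copy()
        start = 0
        for conv, size in zip(self.group_convs, self.spec.groups):
            dx[:, start:start + size] = conv.backward(
                np.ascontiguousarray(dz[:, start:start + size]))
            start += size
        return dx

    def out_shape(self, in_shape):
        c, h, w = in_shape
        if c != self.spec.in_channels:
            raise ShapeError(f"expected {self.spec.in_channels} channels, got {c}")
        return (self.spec.out_channels, h, w)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class EfficientChannelAttention(Layer):
    """ECA gate: GAP -> k-wide 1-D conv across channels -> sigmoid -> rescale.

    Adds exactly ``k`` learnable values (the 1-D kernel, no bias), so the
    attention is parameter-free at printed-budget rounding.
    """

    def __init__(self, config: EcaConfig | int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        if isinstance(config, int):
            config = EcaConfig(channels=config)
        self.config = config
        k = config.kernel_size
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / math.sqrt(k)
        self.weight = self.add_param(
            "weight", rng.uniform(-bound, bound, size=k).astype(dtype))
        self._cache = None

    def forward(self, x):
        c = self.config.channels
        if x.shape[1] != c:
            raise ShapeError(f"expected {c} channels, got {x.shape[1]}")
        k = self.config.kernel_size
        pad = k // 2
        g = x.mean(axis=(2, 3))                               # (n, c)
        # edge padding keeps the gate symmetric under channel permutation of
        # an equal-mean input (zero padding would bias the border channels)
        gp = np.pad(g, ((0, 0), (pad, pad)), mode="edge")
        windows = np.lib.stride_tricks.sliding_window_view(gp, k, axis=1)  # (n, c, k)
        s_pre = windows @ self.weight.data
        s = _sigmoid(s_pre)
        if self.training:
            self._cache = (x, s, windows, x.shape[2] * x.shape[3])
        return x * s[:, :, None, None]

    def backward(self, dy):
        x, s, windows, hw = self._cache
        k = self.config.kernel_size
        pad = k // 2
        c = self.config.channels
        dx = dy * s[:, :, None, None]
        ds = (dy * x).sum(axis=(2, 3))
        ds_pre = ds * s * (1.0 - s)
        self.weight.grad += np.einsum("nck,nc->k", windows, ds_pre, optimize=True)
        dgp = np.zeros((dy.shape[0], c + 2 * pad), dtype=dy.dtype)
        for j in range(k):
            dgp[:, j : j + c] += ds_pre * self.weight.data[j]
        dg = dgp[:, pad : pad + c].copy()
        if pad:  # fold gradients of the edge-replicated entries back
            dg[:, 0] += dgp[:, :pad].sum(axis=1)
            dg[:, -1] += dgp[:, pad + c :].sum(axis=1)
        dx += dg[:, :, None, None] / hw
        return dx

    def out_shape(self, in_shape):
        return in_shape


class PointwiseHead(Layer):
    """FL2PW classifier head: PW1 (-> BN) -> ReLU -> PW2 -> global avg pool."""

    def __init__(self, spec: HeadSpec, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        self.spec = spec
        rng = rng or np.random.default_rng(0)
        self.pw1 = self.add_child(
            "pw1", Conv2d(spec.in_channels, spec.hidden_width, 1, bias=spec.bias,
                          rng=rng, dtype=dtype))
        self.bn = self.add_child("bn", BatchNorm2d(spec.hidden_width, dtype=dtype)) \
            if spec.use_bn else None
        self.act = self.add_child("act", ReLU())
        self.pw2 = self.add_child(
            "pw2", Conv2d(spec.hidden_width, spec.num_classes, 1, bias=spec.bias,
                          rng=rng, dtype=dtype))
        self.gap = self.add_child("gap", GlobalAvgPool2d())

    def forward(self, x):
        if x.shape[1] != self.spec.in_channels:
            raise ShapeError(
                f"expected {self.spec.in_channels} channels, got {x.shape[1]}")
        if x.shape[2] == 0 or x.shape[3] == 0:
            raise ShapeError("head requires a non-empty spatial grid")
        y = self.pw1.forward(x)
        if self.bn is not None:
            y = self.bn.forward(y)
        y = self.act.forward(y)
        y = self.pw2.forward(y)
        return self.gap.forward(y)

    def backward(self, dy):
        dy = self.gap.backward(dy)
        dy = self.pw2.backward(dy)
        dy = self.act.backward(dy)
        if self.bn is not None:
            dy = self.bn.backward(dy)
        return self.pw1.backward(dy)

    def out_shape(self, in_shape):
        return (self.spec.num_classes,)


# ---------------------------------------------------------------------------
# Functional wrappers (seeded one-shot application)
# ---------------------------------------------------------------------------

def partial_conv(x: np.ndarray, spec: PConvSpec, seed: int = 0) -> np.ndarray:
    layer = PartialConv2d(spec, rng=np.random.default_rng(seed)).eval()
    return layer.forward(x)


def pmconv(x: np.ndarray, spec: PMConvSpec, seed: int = 0) -> np.ndarray:
    layer = PartialMixedConv2d(spec, rng=np.random.default_rng(seed)).eval()
    return layer.forward(x)


def eca_attention(x: np.ndarray, config: EcaConfig | int, seed: int = 0) -> np.ndarray:
    layer = EfficientChannelAttention(config, rng=np.random.default_rng(seed)).eval()
    return layer.forward(x)


def fl2pw_head(x: np.ndarray, spec: HeadSpec, seed: int = 0) -> np.ndarray:
    layer = PointwiseHead(spec, rng=np.random.default_rng(seed)).eval()
    return layer.forward(x)
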