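"""Exact parameter and MAC budget accounting for built models.

Parameter counts enumerate every learnable tensor (conv kernels, biases, BN
affine pairs, linear weights, ECA 1-D kernels); parameter memory is the
count x 4 bytes (fp32) expressed in binary MiB, rounded to two decimals —
the convention that reproduces the published "Params (MB)" column.

MAC counts are computed per layer for one forward pass at a stated input
size under an explicit :class:`MacConvention`:

* convolution / linear: output elements x (in_channels / groups x k^2),
  plus one add per output element when the layer has a bias (``bias_adds``);
* elementwise activations and gates: one op per element (``activations``);
* pooling and batch-norm are excluded by default and can be switched on.

The reduction arithmetic ``(x - x1) / x x 100`` used for the published
memory/Flops/inference-speed deltas lives in :func:`percent_reduction`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .architectures import Model
from .core_ops import (EfficientChannelAttention, PartialConv2d,
                       PartialMixedConv2d, PointwiseHead)
from .layers import (BatchNorm2d, Conv2d, Dropout, Flatten, GlobalAvgPool2d,
                     Layer, Linear, MaxPool2d, ReLU, Sequential)

BYTES_PER_PARAM = 4  # fp32
MIB = 2 ** 20


@dataclass(frozen=True)
class MacConvention:
    """Which side terms enter the MAC total, besides conv/linear multiplies."""

    bias_adds: bool = True
    activations: bool = True
    pooling: bool = False
    batchnorm: bool = False

    def describe(self) -> str:
        on = [k for k, v in self.__dict__.items() if v]
        return "macs+" + "+".join(on) if on else "macs-only"


@dataclass
class LayerBudget:
    name: str
    kind: str
    param_count: int
    mac_count: int = 0


@dataclass
class ModelBudget:
    total_params: int
    head_params: int = 0
    total_macs: int = 0
    layers: list[LayerBudget] = field(default_factory=list)
    convention: str = ""

    @property
    def param_memory_mib(self) -> float:
        """Parameter memory in binary MiB at 4 bytes/value, two decimals."""
        return round(self.total_params * BYTES_PER_PARAM / MIB, 2)

    @property
    def macs_m(self) -> float:
        """MACs in millions, two decimals."""
        return round(self.total_macs / 1e6, 2)

    @property
    def head_fraction_pct(self) -> float:
        if self.total_params == 0:
            raise ZeroDivisionError("head fraction undefined for an empty model")
        return round(100.0 * self.head_params / self.total_params, 2)


@dataclass
class ReductionReport:
    """Eq-style relative reduction from a baseline x to an improved x1."""

    x: float
    x1: float

    def __post_init__(self):
        if self.x <= 0:
            raise ValueError(f"baseline quantity must be positive, got {self.x}")

    @property
    def reduction_pct(self) -> float:
        return round(100.0 * (self.x - self.x1) / self.x, 2)


def percent_reduction(x: float, x1: float) -> ReductionReport:
    """Relative reduction (x - x1)/x as a two-decimal percentage."""
    return ReductionReport(x, x1)


# ---------------------------------------------------------------------------
# Parameter counting
# ---------------------------------------------------------------------------

def count_parameters(model: Layer) -> ModelBudget:
    """Enumerate every learnable tensor of the model and sum element counts."""
    layers = []
    if isinstance(model, Model):
        for part_name, part in (("features", model.features), ("head", model.head)):
            for name, layer in part:
                layers.append(LayerBudget(
                    name=f"{part_name}.{name}", kind=type(layer).__name__,
                    param_count=sum(p.size for p in layer.parameters())))
        head_params = sum(p.size for p in model.head.parameters())
    else:
        layers.append(LayerBudget(name="model", kind=type(model).__name__,
                                  param_count=sum(p.size for p in model.parameters())))
        head_params = 0
    total = sum(lb.param_count for lb in layers)
    return ModelBudget(total_params=total, head_params=head_params, layers=layers)


def head_fraction(model: Model) -> float:
    """Share of parameters in the classifier head (percent, two decimals)."""
    return count_parameters(model).head_fraction_pct


# ---------------------------------------------------------------------------
# MAC counting
# ---------------------------------------------------------------------------

def _conv_macs(layer: Conv2d, in_shape, conv: MacConvention) -> int:
    c, h, w = in_shape
    out_el = layer.out_channels * h * w
    macs = out_el * (layer.in_channels // layer.groups) * layer.kernel_size ** 2
    if conv.bias_adds and layer.bias is not None:
        macs += out_el
    return macs


def leaf_macs(layer: Layer, in_shape: tuple, conv: MacConvention) -> int:
    """MACs of a single layer given its (C, H, W) input shape."""
    n_el = 1
    for s in in_shape:
        n_el *= s
    if isinstance(layer, Conv2d):
        return _conv_macs(layer, in_shape, conv)
    if isinstance(layer, Linear):
        macs = layer.in_features * layer.out_features
        if conv.bias_adds and layer.bias is not None:
            macs += layer.out_features
        return macs
    if isinstance(layer, BatchNorm2d):
        return 2 * n_el if conv.batchnorm else 0
    if isinstance(layer, ReLU):
        return n_el if conv.activations else 0
    if isinstance(layer, MaxPool2d):
        return n_el if conv.pooling else 0
    if isinstance(layer, GlobalAvgPool2d):
        return n_el if conv.pooling else 0
    if isinstance(layer, (Dropout, Flatten)):
        return 0
    if isinstance(layer, EfficientChannelAttention):
        c = in_shape[0]
        macs = c * layer.config.kernel_size          # 1-D conv over channels
        if conv.activations:
            macs += c + n_el                         # sigmoid + rescale
        if conv.pooling:
            macs += n_el                             # global average pool
        return macs
    if isinstance(layer, PartialConv2d):
        cp = layer.spec.cp
        macs = _conv_macs(layer.conv_p, (cp, in_shape[1], in_shape[2]), conv)
        macs += _conv_macs(layer.pw, in_shape, conv)
        out_shape = layer.out_shape(in_shape)
        if layer.bn is not None:
            macs += leaf_macs(layer.bn, out_shape, conv)
        macs += leaf_macs(layer.act, out_shape, conv)
        return macs
    if isinstance(layer, PartialMixedConv2d):
        macs = 0
        for g_conv, size in zip(layer.group_convs, layer.spec.groups):
            macs += _conv_macs(g_conv, (size, in_shape[1], in_shape[2]), conv)
        macs += _conv_macs(layer.pw, in_shape, conv)
        out_shape = layer.out_shape(in_shape)
        if layer.bn is not None:
            macs += leaf_macs(layer.bn, out_shape, conv)
        macs += leaf_macs(layer.act, out_shape, conv)
        return macs
    if isinstance(layer, PointwiseHead):
        mid = (layer.spec.hidden_width, in_shape[1], in_shape[2])
        macs = _conv_macs(layer.pw1, in_shape, conv)
        if layer.bn is not None:
            macs += leaf_macs(layer.bn, mid, conv)
        macs += leaf_macs(layer.act, mid, conv)
        macs += _conv_macs(layer.pw2, mid, conv)
        macs += leaf_macs(layer.gap,
                          (layer.spec.num_classes, in_shape[1], in_shape[2]), conv)
        return macs
    raise TypeError(f"no MAC rule for layer type {type(layer).__name__}")


def count_macs(model: Model, input_shape: tuple = (3, 224, 224),
               convention: MacConvention = MacConvention()) -> ModelBudget:
    """Per-layer and total multiply-accumulate count for one forward pass."""
    if any(s is None or s < 1 for s in input_shape):
        raise ValueError(f"input shape must be fully known, got {input_shape}")
    budget = count_parameters(model)
    shape = tuple(input_shape)
    i = 0
    for part in (model.features, model.head):
        for _, layer in part:
            budget.layers[i].mac_count = leaf_macs(layer, shape, convention)
            shape = layer.out_shape(shape)
            i += 1
    budget.total_macs = sum(lb.mac_count for lb in budget.layers)
    budget.convention = convention.describe()
    return budget


def budget_summary(model: Model, input_shape: tuple = (3, 224, 224),
                   convention: MacConvention = MacConvention()) -> dict:
    """JSON-friendly summary: total params, MiB, MACs (M), head share (%)."""
    b = count_macs(model, input_shape, convention)
    return {
        "total_params": b.total_params,
        "param_memory_mib": b.param_memory_mib,
        "macs_m": b.macs_m,
        "head_params": b.head_params,
        "head_fraction_pct": b.head_fraction_pct,
        "mac_convention": b.convention,
    }
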