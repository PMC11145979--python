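"""Declarative builder for the VGG11-derived lightweight model family.

The family is described by :class:`ArchConfig` (channel plan, per-stage
operator, pooling layout, attention placement, head type) and materialised by
:func:`build_model`.  Six presets cover the published ablation grid:

========== ======================================================== =========
preset     description                                              options
========== ======================================================== =========
vgg11      classic configuration-A baseline (no BN, 4096-wide FCs)  --
re_vgg11   reduced channel plan (32..256, 1024-wide FCs) + BN       --
scheme1    re_vgg11 with partial convolutions in stages 2-8         a
scheme2    scheme1 with the two-pointwise-conv + GAP head           a b
scheme3    scheme2 with mixed-kernel partial conv in stages 7-8     a b c
g_ppw_vgg11  scheme3 with ECA attention after every stage           a b c d
========== ======================================================= ==========

Options: (a) PConv, (b) FL2PWConv head, (c) PMConv, (d) ECANet.

Bias/normalisation conventions differ between the dense baselines and the
partial-conv presets (conv biases in the baselines; bias-free convs under BN
and an affine-free head in the lightweight presets).  These conventions are
part of the preset definitions: they are what reproduces the published
parameter budgets to the printed 0.01 MiB.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .core_ops import (EcaConfig, EfficientChannelAttention, HeadSpec,
                       PartialConv2d, PartialMixedConv2d, PConvSpec,
                       PMConvSpec, PointwiseHead)
from .layers import (BatchNorm2d, ConfigError, Conv2d, Dropout, Flatten,
                     Layer, Linear, MaxPool2d, ReLU, Sequential)

VGG_PLAN = (64, 128, 256, 256, 512, 512, 512, 512)
RE_PLAN = (32, 64, 64, 64, 128, 128, 256, 256)
POOL_AFTER = (1, 2, 4, 6, 8)       # classic VGG11 pooling layout (1-based stages)
N_STAGES = 8
N_POOLS = len(POOL_AFTER)

STAGE_OPS = ("dense", "pconv", "pmconv")
HEADS = ("fc", "fl2pw")


@dataclass(frozen=True)
class ArchConfig:
    """Full architecture description; every preset resolves to one of these."""

    channel_plan: tuple[int, ...] = RE_PLAN
    stage_ops: tuple[str, ...] = ("dense",) * N_STAGES
    pool_after: tuple[int, ...] = POOL_AFTER
    use_bn: bool = True
    conv_bias: bool = True
    partial_ratio: float = 0.25
    pmconv_kernels: tuple[int, ...] = (3, 5, 7)
    eca_stages: tuple[int, ...] = ()
    eca_gamma: int = 2
    eca_b: int = 1
    eca_k_min: int = 3
    head: str = "fc"
    fc_widths: tuple[int, ...] = (1024, 1024)
    head_bias: bool = True
    head_bn: bool = True
    dropout: float = 0.5
    num_classes: int = 6
    input_size: int = 224

    def __post_init__(self):
        if len(self.channel_plan) != N_STAGES:
            raise ConfigError(f"channel plan must list {N_STAGES} stages")
        if len(self.stage_ops) != N_STAGES:
            raise ConfigError(f"stage ops must list {N_STAGES} stages")
        for op in self.stage_ops:
            if op not in STAGE_OPS:
                raise ConfigError(f"unknown stage op {op!r}")
        if self.head not in HEADS:
            raise ConfigError(f"unknown head {self.head!r}")
        if any(c < 1 for c in self.channel_plan):
            raise ConfigError("channel widths must be positive")
        if self.num_classes < 2:
            raise ConfigError("need at least two classes")
        if self.input_size % (2 ** N_POOLS) != 0 or self.input_size < 2 ** N_POOLS:
            raise ConfigError(
                f"input size must be a positive multiple of {2 ** N_POOLS}")
        if set(self.pool_after) - set(range(1, N_STAGES + 1)):
            raise ConfigError("pool stages out of range")
        if set(self.eca_stages) - set(range(1, N_STAGES + 1)):
            raise ConfigError("ECA stages out of range")

    @property
    def final_grid(self) -> int:
        """Spatial side length after all pools (7 for 224 input)."""
        return self.input_size // (2 ** len(self.pool_after))

    @property
    def option_flags(self) -> dict[str, bool]:
        """The (a) PConv / (b) FL2PW head / (c) PMConv / (d) ECA grid."""
        return {
            "a": any(op in ("pconv", "pmconv") for op in self.stage_ops),
            "b": self.head == "fl2pw",
            "c": "pmconv" in self.stage_ops,
            "d": bool(self.eca_stages),
        }

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "ArchConfig":
        kwargs = dict(d)
        for k in ("channel_plan", "stage_ops", "pool_after", "pmconv_kernels",
                  "eca_stages", "fc_widths"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ArchConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _pconv_ops(pm_stages: tuple[int, ...] = ()) -> tuple[str, ...]:
    # stage 1 stays dense: 3 input channels cannot be meaningfully split
    ops = ["dense"] + ["pconv"] * (N_STAGES - 1)
    for s in pm_stages:
        ops[s - 1] = "pmconv"
    return tuple(ops)


PRESETS: dict[str, ArchConfig] = {
    "vgg11": ArchConfig(
        channel_plan=VGG_PLAN, use_bn=False, conv_bias=True,
        fc_widths=(4096, 4096)),
    "re_vgg11": ArchConfig(
        channel_plan=RE_PLAN, use_bn=True, conv_bias=True,
        fc_widths=(1024, 1024)),
    "scheme1": ArchConfig(
        channel_plan=RE_PLAN, stage_ops=_pconv_ops(), use_bn=True,
        conv_bias=False, fc_widths=(1024, 1024)),
    "scheme2": ArchConfig(
        channel_plan=RE_PLAN, stage_ops=_pconv_ops(), use_bn=True,
        conv_bias=False, head="fl2pw", fc_widths=(1024, 1024),
        head_bias=False, head_bn=False),
    "scheme3": ArchConfig(
        channel_plan=RE_PLAN, stage_ops=_pconv_ops((7, 8)), use_bn=True,
        conv_bias=False, head="fl2pw", fc_widths=(1024, 1024),
        head_bias=False, head_bn=False),
    "g_ppw_vgg11": ArchConfig(
        channel_plan=RE_PLAN, stage_ops=_pconv_ops((7, 8)), use_bn=True,
        conv_bias=False, head="fl2pw", fc_widths=(1024, 1024),
        head_bias=False, head_bn=False,
        eca_stages=tuple(range(1, N_STAGES + 1))),
}


def get_preset(name: str, num_classes: int = 6, input_size: int = 224) -> ArchConfig:
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return dataclasses.replace(PRESETS[name], num_classes=num_classes,
                               input_size=input_size)


def list_presets() -> dict[str, dict[str, bool]]:
    """Preset names with their resolved (a)/(b)/(c)/(d) option flags."""
    return {name: cfg.option_flags for name, cfg in PRESETS.items()}


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class Model(Layer):
    """A built network: ``features`` (8 conv stages + pools) then ``head``."""

    def __init__(self, config: ArchConfig, features: Sequential, head: Sequential):
        super().__init__()
        self.config = config
        self.features = self.add_child("features", features)
        self.head = self.add_child("head", head)

    def forward(self, x):
        return self.head.forward(self.features.forward(x))

    def backward(self, dy):
        return self.features.backward(self.head.backward(dy))

    def out_shape(self, in_shape):
        return self.head.out_shape(self.features.out_shape(in_shape))

    # -- introspection ----------------------------------------------------
    def summary(self) -> list[dict]:
        """Per top-level layer: name, type, output shape, parameter count."""
        rows = []
        shape = (3, self.config.input_size, self.config.input_size)
        for part in (self.features, self.head):
            for name, layer in part:
                shape = layer.out_shape(shape)
                rows.append({
                    "layer": name,
                    "type": type(layer).__name__,
                    "out_shape": "x".join(str(s) for s in shape),
                    "params": sum(p.size for p in layer.parameters()),
                })
        return rows

    def summary_csv(self, path=None) -> str:
        buf = io.StringIO()
        buf.write("layer,type,out_shape,params\n")
        for row in self.summary():
            buf.write(f"{row['layer']},{row['type']},{row['out_shape']},{row['params']}\n")
        text = buf.getvalue()
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    # -- checkpointing ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        for path, layer in _walk(self):
            if isinstance(layer, BatchNorm2d):
                state[f"{path}.running_mean"] = layer.running_mean
                state[f"{path}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            p.data = np.array(state[name], dtype=p.data.dtype)
        for path, layer in _walk(self):
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = np.array(state[f"{path}.running_mean"],
                                              dtype=layer.running_mean.dtype)
                layer.running_var = np.array(state[f"{path}.running_var"],
                                             dtype=layer.running_var.dtype)

    def save(self, path):
        np.savez(path, __config__=json.dumps(self.to_config_dict()),
                 **self.state_dict())

    def to_config_dict(self) -> dict:
        return self.config.to_dict()

    @classmethod
    def load(cls, path) -> "Model":
        with np.load(path, allow_pickle=False) as npz:
            config = ArchConfig.from_dict(json.loads(str(npz["__config__"])))
            model = build_model(config)
            model.load_state_dict({k: npz[k] for k in npz.files if k != "__config__"})
        return model.eval()


def _walk(layer: Layer, prefix: str = ""):
    for name, child in layer._children:
        path = name if not prefix else f"{prefix}.{name}"
        yield path, child
        yield from _walk(child, path)


def build_model(preset_or_config: str | ArchConfig, seed: int = 0,
                num_classes: int | None = None, input_size: int | None = None,
                dtype=np.float32) -> Model:
    """Materialise a trainable model from a preset name or an ArchConfig."""
    if isinstance(preset_or_config, str):
        cfg = get_preset(preset_or_config,
                         num_classes=num_classes if num_classes is not None else 6,
                         input_size=input_size if input_size is not None else 224)
    else:
        cfg = preset_or_config
        if num_classes is not None or input_size is not None:
            cfg = dataclasses.replace(
                cfg,
                num_classes=num_classes if num_classes is not None else cfg.num_classes,
                input_size=input_size if input_size is not None else cfg.input_size)
    rng = np.random.default_rng(seed)

    features = Sequential()
    in_ch = 3
    for stage in range(1, N_STAGES + 1):
        out_ch = cfg.channel_plan[stage - 1]
        op = cfg.stage_ops[stage - 1]
        if op == "dense":
            features.append(f"stage{stage}_conv",
                            Conv2d(in_ch, out_ch, 3, bias=cfg.conv_bias, rng=rng,
                                   dtype=dtype))
            if cfg.use_bn:
                features.append(f"stage{stage}_bn", BatchNorm2d(out_ch, dtype=dtype))
            features.append(f"stage{stage}_relu", ReLU())
        elif op == "pconv":
            spec = PConvSpec(in_ch, out_ch, cfg.partial_ratio)
            features.append(f"stage{stage}_pconv",
                            PartialConv2d(spec, use_bn=cfg.use_bn,
                                          pw_bias=cfg.conv_bias, rng=rng, dtype=dtype))
        else:  # pmconv
            spec = PMConvSpec(in_ch, out_ch, cfg.partial_ratio,
                              kernel_set=cfg.pmconv_kernels)
            features.append(f"stage{stage}_pmconv",
                            PartialMixedConv2d(spec, use_bn=cfg.use_bn,
                                               pw_bias=cfg.conv_bias, rng=rng,
                                               dtype=dtype))
        if stage in cfg.eca_stages:
            eca_cfg = EcaConfig(out_ch, cfg.eca_gamma, cfg.eca_b, cfg.eca_k_min)
            features.append(f"stage{stage}_eca",
                            EfficientChannelAttention(eca_cfg, rng=rng, dtype=dtype))
        if stage in cfg.pool_after:
            features.append(f"stage{stage}_pool", MaxPool2d())
        in_ch = out_ch

    head = Sequential()
    last_ch = cfg.channel_plan[-1]
    if cfg.head == "fc":
        grid = cfg.final_grid
        widths = [last_ch * grid * grid, *cfg.fc_widths]
        head.append("flatten", Flatten())
        for i in range(len(cfg.fc_widths)):
            head.append(f"fc{i + 1}", Linear(widths[i], widths[i + 1], rng=rng,
                                             dtype=dtype))
            head.append(f"fc{i + 1}_relu", ReLU())
            if cfg.dropout > 0:
                head.append(f"fc{i + 1}_drop", Dropout(cfg.dropout, rng=rng))
        head.append("fc_out", Linear(widths[-1], cfg.num_classes, rng=rng, dtype=dtype))
    else:
        spec = HeadSpec(last_ch, cfg.fc_widths[0], cfg.num_classes,
                        bias=cfg.head_bias, use_bn=cfg.head_bn)
        head.append("fl2pw", PointwiseHead(spec, rng=rng, dtype=dtype))

    return Model(cfg, features, head)
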