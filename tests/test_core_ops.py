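"""Operator contracts: PConv, PMConv, ECA kernel rule and gate, FL2PW head."""

import math

import numpy as np
import pytest

from gppwvgg.core_ops import (EcaConfig, EfficientChannelAttention, HeadSpec,
                              PartialConv2d, PartialMixedConv2d, PConvSpec,
                              PMConvSpec, PointwiseHead, eca_kernel_size,
                              split_groups)
from gppwvgg.layers import ConfigError, Conv2d, ShapeError
from tests.test_layers import check_layer_gradients


def _param_count(layer):
    return sum(p.size for p in layer.parameters())


# ---------------------------------------------------------------------------
# ECA kernel rule
# ---------------------------------------------------------------------------

def eca_kernel_brute_force(c, gamma=2, b=1, k_min=3):
    """Direct restatement of the adaptive-kernel rule, kept independent."""
    t = int(abs(math.log2(c) + b) // gamma)
    if t % 2 == 0:
        t += 1
    return t if t >= k_min else k_min


def test_eca_kernel_size_agrees_with_brute_force_table():
    for c in range(1, 4097):
        assert eca_kernel_size(c) == eca_kernel_brute_force(c), f"C={c}"


@pytest.mark.parametrize("c,expected", [(256, 5), (32, 3), (4, 3), (1, 3),
                                        (1024, 5), (2048, 7)])
def test_eca_kernel_size_examples(c, expected):
    assert eca_kernel_size(c) == expected


def test_eca_kernel_size_is_odd_and_clamped():
    for c in (1, 2, 3, 7, 100, 513):
        k = eca_kernel_size(c)
        assert k % 2 == 1 and k >= 3


# ---------------------------------------------------------------------------
# Partial convolution
# ---------------------------------------------------------------------------

def test_partial_conv_shape_contract(rng):
    spec = PConvSpec(64, 64, partial_ratio=0.25)
    layer = PartialConv2d(spec, rng=rng).eval()
    x = rng.normal(size=(2, 64, 16, 16)).astype(np.float32)
    assert layer.forward(x).shape == (2, 64, 16, 16)
    assert spec.cp == 16


def test_partial_conv_parameter_count_in64_out64():
    # 3x3 on the 16-channel subset + 1x1 mix with bias + BN affine pair
    spec = PConvSpec(64, 64, partial_ratio=0.25, kernel=3)
    layer = PartialConv2d(spec, use_bn=True, pw_bias=True)
    assert _param_count(layer) == 9 * 16 ** 2 + 64 * 64 + 64 + 2 * 64 == 6592


def test_partial_conv_full_ratio_equals_dense_composition(rng):
    """r=1 must coincide with dense kxk conv -> pointwise, same weights."""
    spec = PConvSpec(8, 10, partial_ratio=1.0, kernel=3)
    layer = PartialConv2d(spec, use_bn=False, pw_bias=True,
                          rng=rng, dtype=np.float64).eval()
    dense = Conv2d(8, 8, 3, bias=False, dtype=np.float64).eval()
    pw = Conv2d(8, 10, 1, bias=True, dtype=np.float64).eval()
    dense.weight.data = layer.conv_p.weight.data.copy()
    pw.weight.data = layer.pw.weight.data.copy()
    pw.bias.data = layer.pw.bias.data.copy()
    x = rng.normal(size=(3, 8, 16, 16))
    got = layer.forward(x)
    want = np.maximum(pw.forward(dense.forward(x)), 0)  # layer ends in ReLU
    assert np.abs(got - want).max() < 1e-5


def test_partial_conv_errors(rng):
    with pytest.raises(ConfigError):
        PConvSpec(64, 64, partial_ratio=0.001)  # cp floors to zero
    with pytest.raises(ConfigError):
        PConvSpec(64, 64, kernel=4)
    layer = PartialConv2d(PConvSpec(8, 8), rng=rng)
    with pytest.raises(ShapeError):
        layer.forward(np.zeros((1, 9, 8, 8), np.float32))


def test_partial_conv_gradients(rng):
    layer = PartialConv2d(PConvSpec(4, 5, partial_ratio=0.5), use_bn=True,
                          rng=rng, dtype=np.float64)
    check_layer_gradients(layer, rng.normal(size=(2, 4, 4, 4)))


# ---------------------------------------------------------------------------
# Partially mixed convolution
# ---------------------------------------------------------------------------

def test_split_groups_examples():
    assert split_groups(64, 3) == [21, 21, 22]
    assert split_groups(32, 3) == [10, 11, 11]
    assert split_groups(9, 3) == [3, 3, 3]


def test_pmconv_shape_contract(rng):
    spec = PMConvSpec(256, 256, partial_ratio=0.25, kernel_set=(3, 5, 7))
    layer = PartialMixedConv2d(spec, rng=rng).eval()
    x = rng.normal(size=(1, 256, 7, 7)).astype(np.float32)
    assert layer.forward(x).shape == (1, 256, 7, 7)


def test_pmconv_single_kernel_group_equals_partial_conv(rng):
    """kernel_set={3} with one group degenerates exactly to PConv."""
    pm = PartialMixedConv2d(PMConvSpec(8, 12, 0.5, kernel_set=(3,)),
                            use_bn=True, rng=rng, dtype=np.float64)
    pc = PartialConv2d(PConvSpec(8, 12, 0.5, kernel=3), use_bn=True,
                       dtype=np.float64)
    pc.conv_p.weight.data = pm.group_convs[0].weight.data.copy()
    pc.pw.weight.data = pm.pw.weight.data.copy()
    pc.pw.bias.data = pm.pw.bias.data.copy()
    pm.eval(), pc.eval()
    x = rng.normal(size=(2, 8, 6, 6))
    np.testing.assert_array_equal(pm.forward(x), pc.forward(x))


def test_pmconv_parameter_delta_over_partial_conv():
    """Replacing the partial 3x3 stage by {3,5,7} groups at cp=64: +1,846."""
    pm = PartialMixedConv2d(PMConvSpec(256, 256, 0.25, kernel_set=(3, 5, 7)),
                            use_bn=False, pw_bias=False)
    pc = PartialConv2d(PConvSpec(256, 256, 0.25), use_bn=False, pw_bias=False)
    delta = _param_count(pm) - _param_count(pc)
    assert delta == (9 * 21 ** 2 + 25 * 21 ** 2 + 49 * 22 ** 2) - 9 * 64 ** 2 == 1846


def test_pmconv_config_errors():
    with pytest.raises(ConfigError):
        PMConvSpec(64, 64, kernel_set=(3, 4))        # even kernel
    with pytest.raises(ConfigError):
        PMConvSpec(64, 64, kernel_set=(3, 3))        # duplicate kernels
    with pytest.raises(ConfigError):
        PMConvSpec(64, 64, kernel_set=(3, 5), group_plan=(8, 9))  # != cp
    with pytest.raises(ConfigError):
        PMConvSpec(8, 8, partial_ratio=0.25, kernel_set=(3, 5, 7))  # cp < groups


def test_pmconv_gradients(rng):
    layer = PartialMixedConv2d(
        PMConvSpec(6, 6, 0.5, kernel_set=(1, 3)), use_bn=True,
        rng=rng, dtype=np.float64)
    check_layer_gradients(layer, rng.normal(size=(2, 6, 4, 4)))


# ---------------------------------------------------------------------------
# ECA attention gate
# ---------------------------------------------------------------------------

def test_eca_weights_are_in_unit_interval_and_uniform_for_equal_means(rng):
    layer = EfficientChannelAttention(EcaConfig(16), rng=rng,
                                      dtype=np.float64).eval()
    # equal per-channel means -> identical gates across channels
    x = np.tile(rng.normal(size=(1, 1, 8, 8)), (2, 16, 1, 1))
    y = layer.forward(x)
    gate_per_channel = y.sum(axis=(2, 3)) / x.sum(axis=(2, 3))
    np.testing.assert_allclose(gate_per_channel, gate_per_channel[0, 0],
                               atol=1e-12)
    assert ((gate_per_channel > 0) & (gate_per_channel < 1)).all()


def test_eca_preserves_sign_pattern(rng):
    layer = EfficientChannelAttention(8, rng=rng, dtype=np.float64).eval()
    x = rng.normal(size=(2, 8, 5, 5))
    y = layer.forward(x)
    np.testing.assert_array_equal(np.sign(y), np.sign(x))


def test_eca_parameter_count_is_kernel_size():
    for c in (8, 64, 256, 1024):
        layer = EfficientChannelAttention(c)
        assert _param_count(layer) == eca_kernel_size(c)


def test_eca_saturated_gate_recovers_input(rng):
    layer = EfficientChannelAttention(8, rng=rng, dtype=np.float64).eval()
    layer.weight.data[:] = 100.0  # drives sigmoid -> 1 for positive-mean input
    x = np.abs(rng.normal(size=(1, 8, 6, 6))) + 0.5
    assert np.abs(layer.forward(x) - x).max() < 1e-3


def test_eca_channel_mismatch_raises(rng):
    layer = EfficientChannelAttention(8, rng=rng)
    with pytest.raises(ShapeError):
        layer.forward(np.zeros((1, 9, 4, 4), np.float32))


def test_eca_gradients(rng):
    layer = EfficientChannelAttention(EcaConfig(6), rng=rng, dtype=np.float64)
    check_layer_gradients(layer, rng.normal(size=(2, 6, 4, 4)))


# ---------------------------------------------------------------------------
# FL2PW head
# ---------------------------------------------------------------------------

def test_head_shape_contract(rng):
    head = PointwiseHead(HeadSpec(256, 1024, 6), rng=rng).eval()
    x = rng.normal(size=(4, 256, 7, 7)).astype(np.float32)
    assert head.forward(x).shape == (4, 6)


def test_head_parameter_count():
    head = PointwiseHead(HeadSpec(256, 1024, 6, bias=True, use_bn=True))
    assert _param_count(head) == (256 * 1024 + 1024) + 2 * 1024 + (1024 * 6 + 6) \
        == 271366


def test_head_zero_weights_give_constant_bias_output(rng):
    head = PointwiseHead(HeadSpec(8, 16, 4, bias=True, use_bn=False),
                         rng=rng, dtype=np.float64).eval()
    head.pw2.weight.data[:] = 0.0
    head.pw2.bias.data[:] = np.arange(4.0)
    y = head.forward(rng.normal(size=(3, 8, 5, 5)))
    np.testing.assert_allclose(y, np.tile(np.arange(4.0), (3, 1)), atol=1e-12)


def test_head_empty_grid_raises(rng):
    head = PointwiseHead(HeadSpec(8, 16, 4), rng=rng)
    with pytest.raises(ShapeError):
        head.forward(np.zeros((1, 8, 0, 5), np.float32))


def test_head_gradients(rng):
    head = PointwiseHead(HeadSpec(3, 5, 2, bias=True, use_bn=True),
                         rng=rng, dtype=np.float64)
    check_layer_gradients(head, rng.normal(size=(2, 3, 3, 3)))


def test_operators_are_deterministic(rng):
    x = rng.normal(size=(2, 16, 8, 8)).astype(np.float32)
    a = PartialConv2d(PConvSpec(16, 16), rng=np.random.default_rng(5)).eval()
    b = PartialConv2d(PConvSpec(16, 16), rng=np.random.default_rng(5)).eval()
    np.testing.assert_array_equal(a.forward(x), b.forward(x))
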