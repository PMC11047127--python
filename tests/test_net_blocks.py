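"""Encoder blocks, SegPath and network assembly against scalar-loop oracles."""

import numpy as np
import pytest

from afmsnet import autodiff as ad
from afmsnet.autodiff import Tensor
from afmsnet.net_blocks import (DAEB, SAEB, Conv3d, NetworkSpec, SegPath,
                                ValidationError, build_network,
                                count_parameters)
from oracles import (daeb_params, loop_daeb, loop_saeb, loop_segpath,
                     saeb_params, segpath_branches)


def _random_case(seed):
    rng = np.random.default_rng(seed)
    c_in = int(rng.integers(1, 4))
    c_out = int(rng.integers(1, 5)) * 2  # even, divisible by reduction 2
    shape = (1, int(rng.integers(1, 4)), int(rng.integers(1, 4)),
             int(rng.integers(1, 4)), c_in)
    x = rng.normal(size=shape)
    return rng, x, c_in, c_out


@pytest.mark.parametrize("seed", range(25))
def test_saeb_matches_scalar_loop_oracle(seed):
    rng, x, c_in, c_out = _random_case(seed)
    block = SAEB(c_in, c_out, reduction=2, rng=rng)
    # nonzero beta/bias so the oracle exercises every term
    block.bn.beta.data = rng.normal(size=c_out).astype(np.float32)
    block.conv.b.data = rng.normal(size=c_out).astype(np.float32)
    got = block(Tensor(x), training=True).data
    want = loop_saeb(x, saeb_params(block))
    assert np.abs(got - want).max() < 1e-4


@pytest.mark.parametrize("seed", range(25))
def test_daeb_matches_scalar_loop_oracle(seed):
    rng, x, c_in, c_out = _random_case(seed)
    block = DAEB(c_in, c_out, reduction=2, spatial_kernel=3, rng=rng)
    block.conv.b.data = rng.normal(size=c_out).astype(np.float32)
    got = block(Tensor(x), training=True).data
    want = loop_daeb(x, daeb_params(block))
    assert np.abs(got - want).max() < 1e-4


@pytest.mark.parametrize("seed", range(25))
def test_segpath_matches_scalar_loop_oracle(seed):
    rng, x, c_in, _ = _random_case(seed)
    n = int(rng.integers(1, 4))
    block = SegPath(c_in, n, rng)
    got = block(Tensor(x), training=True).data
    want = loop_segpath(x, segpath_branches(block))
    assert np.abs(got - want).max() < 1e-4


# ---------------------------------------------------------------------------
# Degenerate / identity behaviour
# ---------------------------------------------------------------------------

def test_saeb_zero_input_gives_zero_output_and_uniform_attention(rng):
    block = SAEB(2, 4, reduction=2, rng=rng)
    x = Tensor(np.zeros((1, 2, 2, 2, 2)))
    assert np.all(block(x, training=True).data == 0)
    a = block.attention_weights(x, training=True)
    assert np.allclose(a, 0.25, atol=1e-6)  # uniform over 4 channels


def test_daeb_zero_input_gives_zero_output(rng):
    block = DAEB(2, 4, reduction=2, spatial_kernel=3, rng=rng)
    out = block(Tensor(np.zeros((1, 2, 2, 2, 2))), training=True)
    assert np.all(out.data == 0)


def test_segpath_identity_and_zero_weight_cases(rng):
    x = rng.normal(size=(1, 3, 3, 3, 2))
    assert np.array_equal(SegPath(2, 0, rng)(Tensor(x)).data,
                          np.asarray(x, dtype=np.float32))
    block = SegPath(2, 1, rng)
    for br in block.branches:
        br["c1"].w.data[:] = 0
        br["c3"].w.data[:] = 0
        br["bn1"].beta.data[:] = 0
        br["bn3"].beta.data[:] = 0
    assert np.all(block(Tensor(x), training=True).data == 0)


def test_blocks_reject_nonfinite_input(rng):
    bad = np.full((1, 2, 2, 2, 2), np.nan)
    for block in (SAEB(2, 4, 2, rng), DAEB(2, 4, 2, 3, rng), SegPath(2, 1, rng)):
        with pytest.raises(ValidationError):
            block(Tensor(bad))


# ---------------------------------------------------------------------------
# Attention-map invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(10))
def test_saeb_attention_is_a_channel_distribution(seed):
    rng = np.random.default_rng(seed)
    block = SAEB(3, 8, reduction=4, rng=rng)
    x = Tensor(rng.normal(size=(2, 3, 3, 3, 3)) * rng.uniform(0.1, 10))
    a = block.attention_weights(x, training=True)
    assert np.all(a >= 0)
    assert np.abs(a.sum(axis=1) - 1.0).max() < 1e-6


@pytest.mark.parametrize("seed", range(10))
def test_daeb_attention_maps_lie_in_unit_interval(seed):
    rng = np.random.default_rng(seed)
    block = DAEB(3, 8, reduction=4, spatial_kernel=3, rng=rng)
    x = Tensor(rng.normal(size=(2, 4, 4, 4, 3)) * rng.uniform(0.1, 10))
    ca, sa = block.attention_maps(x)
    for m in (ca, sa):
        assert m.min() >= 0.0 and m.max() <= 1.0


def test_blocks_preserve_spatial_shape_and_finiteness(rng):
    x = Tensor(rng.normal(size=(1, 4, 6, 2, 3)))
    for block, c_out in ((SAEB(3, 8, 2, rng), 8), (DAEB(3, 8, 2, 3, rng), 8),
                         (SegPath(3, 2, rng), 3)):
        out = block(x, training=True)
        assert out.shape == (1, 4, 6, 2, c_out)
        assert np.all(np.isfinite(out.data))


def test_segpath_gradient_reaches_skip_input(rng):
    block = SegPath(3, 2, rng)
    x = Tensor(rng.normal(size=(1, 3, 3, 3, 3)), requires_grad=True)
    ad.sum_(block(x, training=True) ** 2.0).backward()
    assert x.grad is not None and np.abs(x.grad).max() > 0


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------

def _mini_spec(variant="SAEB"):
    return NetworkSpec(variant=variant, n_stages=2, base_channels=4,
                       segpath_iterations=[2, 1], n_classes=3, input_channels=2)


def test_network_output_shape_and_probability_head(rng):
    net = build_network(_mini_spec(), seed=5)
    x = rng.normal(size=(1, 32, 32, 32, 2)).astype(np.float32)
    out = net.forward(x)
    assert out.shape == (1, 32, 32, 32, 3)
    assert np.abs(out.data.sum(axis=-1) - 1.0).max() < 1e-6


def test_network_build_is_deterministic_for_fixed_seed():
    a = build_network(_mini_spec(), seed=11)
    b = build_network(_mini_spec(), seed=11)
    for pa, pb in zip(a.params(), b.params()):
        assert np.array_equal(pa.data, pb.data)
    c = build_network(_mini_spec(), seed=12)
    assert any(not np.array_equal(pa.data, pc.data)
               for pa, pc in zip(a.params(), c.params()))


def test_network_rejects_indivisible_spatial_dims(rng):
    net = build_network(_mini_spec(), seed=0)
    with pytest.raises(ValidationError, match="divisible"):
        net.forward(rng.normal(size=(1, 30, 32, 32, 2)))


def test_single_conv_parameter_hand_count(rng):
    conv = Conv3d(2, 3, 1, rng)
    assert sum(p.size for p in conv.params()) == 2 * 3 + 3


@pytest.mark.parametrize("base,stages", [(4, 2), (8, 3), (16, 4)])
def test_daeb_variant_has_more_parameters_than_saeb(base, stages):
    kw = dict(n_stages=stages, base_channels=base,
              segpath_iterations=[1] * stages, n_classes=4, input_channels=3)
    n_saeb = count_parameters(build_network(NetworkSpec(variant="SAEB", **kw), 0))
    n_daeb = count_parameters(build_network(NetworkSpec(variant="DAEB", **kw), 0))
    assert n_daeb > n_saeb


def test_parameter_count_grows_with_width():
    small = count_parameters(build_network(_mini_spec(), 0))
    spec = _mini_spec()
    spec.base_channels *= 2
    assert count_parameters(build_network(spec, 0)) > small
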