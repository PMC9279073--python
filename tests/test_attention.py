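"""Shuffle-Attention and ECA behaviour against scalar-loop references."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselfuse import attention as att
from vesselfuse.attention import (ECA, ECAParams, SAParams, ShuffleAttention,
                                  ConfigurationError, eca, eca_kernel_size,
                                  global_avg_pool, shuffle_attention)
from vesselfuse.autograd import Tensor

from _oracles import (channel_branch_oracle, eca_kernel_size_oracle,
                      eca_oracle, gap_oracle, shuffle_attention_oracle,
                      spatial_branch_oracle)


class TestGlobalAvgPool:
    def test_constant_map(self):
        x = np.full((1, 1, 5, 7), 2.0)
        np.testing.assert_allclose(global_avg_pool(x), [[2.0]])

    def test_hand_sum(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 1, 2, 2)
        np.testing.assert_allclose(global_avg_pool(x), [[2.5]])

    def test_identity_at_unit_spatial(self, rng):
        v = rng.normal(size=(2, 6, 1, 1))
        np.testing.assert_allclose(global_avg_pool(v), v[:, :, 0, 0])

    def test_matches_loop_oracle(self, rng):
        x = rng.normal(size=(2, 3, 4, 3))
        np.testing.assert_allclose(global_avg_pool(x), gap_oracle(x),
                                   atol=1e-12)


class TestChannelBranch:
    def test_zero_gate_halves_input(self, rng):
        x = rng.normal(size=(1, 3, 2, 2))
        out = att.channel_attention_branch(x, np.zeros(3), np.zeros(3))
        np.testing.assert_allclose(out, 0.5 * x)

    def test_saturated_gate_is_identity(self, rng):
        x = rng.normal(size=(1, 2, 3, 3))
        out = att.channel_attention_branch(x, np.zeros(2), np.full(2, 50.0))
        np.testing.assert_allclose(out, x, rtol=1e-7)

    def test_matches_loop_oracle(self, rng):
        x = rng.normal(size=(1, 2, 3, 3))
        out = att.channel_attention_branch(x, np.ones(2), np.ones(2))
        np.testing.assert_allclose(
            out, channel_branch_oracle(x, np.ones(2), np.ones(2)), atol=1e-10)

    def test_rejects_length_mismatch(self, rng):
        x = rng.normal(size=(1, 3, 2, 2))
        with pytest.raises(ConfigurationError):
            att.channel_attention_branch(x, np.zeros(2), np.zeros(2))


class TestSpatialBranch:
    def test_constant_map_gates_at_bias(self, rng):
        # GN of a spatially constant channel is 0, so the gate is sigmoid(b2)
        x = np.full((1, 2, 3, 3), 1.7)
        b2 = np.array([0.3, -1.2])
        out = att.spatial_attention_branch(x, np.ones(2) * 5.0, b2)
        expect = x * (1 / (1 + np.exp(-b2)))[None, :, None, None]
        np.testing.assert_allclose(out, expect, rtol=1e-6)

    def test_zero_gate_halves_input(self, rng):
        x = rng.normal(size=(1, 2, 3, 3))
        out = att.spatial_attention_branch(x, np.zeros(2), np.zeros(2))
        np.testing.assert_allclose(out, 0.5 * x)

    def test_matches_loop_oracle(self, rng):
        x = rng.normal(size=(2, 2, 3, 4))
        w2, b2 = rng.normal(size=2), rng.normal(size=2)
        np.testing.assert_allclose(
            att.spatial_attention_branch(x, w2, b2),
            spatial_branch_oracle(x, w2, b2), atol=1e-9)


class TestShuffleAttention:
    def test_output_shape_preserved(self, rng):
        p = SAParams.neutral(8, 2)
        x = rng.normal(size=(2, 8, 4, 4))
        assert shuffle_attention(x, p).shape == x.shape

    def test_single_group_equals_branch_concat(self, rng):
        x = rng.normal(size=(1, 4, 3, 3))
        p = SAParams.neutral(4, 1, shuffle=False)
        out = shuffle_attention(x, p)
        top = att.channel_attention_branch(x[:, :2], p.channel_gate_weight,
                                           p.channel_gate_bias)
        bot = att.spatial_attention_branch(x[:, 2:], p.spatial_gate_weight,
                                           p.spatial_gate_bias)
        np.testing.assert_allclose(out, np.concatenate([top, bot], axis=1))

    @pytest.mark.parametrize("channels,groups", [(4, 1), (8, 2), (8, 1)])
    def test_matches_unrolled_oracle(self, rng, channels, groups):
        half = channels // (2 * groups)
        w1, b1 = rng.normal(size=half), rng.normal(size=half)
        w2, b2 = rng.normal(size=half), rng.normal(size=half)
        p = SAParams(groups, w1, b1, w2, b2)
        x = rng.normal(size=(2, channels, 2, 2))
        expect = shuffle_attention_oracle(x, groups, w1, b1, w2, b2)
        np.testing.assert_allclose(shuffle_attention(x, p), expect, atol=1e-9)

    def test_module_agrees_with_functional(self, rng):
        mod = ShuffleAttention(8, groups=2)
        for par in (mod.cweight, mod.cbias, mod.sweight, mod.sbias):
            par.data = rng.normal(size=par.data.shape).astype(np.float32)
        p = SAParams(2, mod.cweight.data.ravel(), mod.cbias.data.ravel(),
                     mod.sweight.data.ravel(), mod.sbias.data.ravel())
        x = rng.normal(size=(1, 8, 4, 4)).astype(np.float32)
        np.testing.assert_allclose(mod(Tensor(x)).data,
                                   shuffle_attention(x, p), atol=1e-5)

    def test_indivisible_channels_name_c_and_g(self):
        with pytest.raises(ConfigurationError, match="C=6.*G=2|6.*4"):
            shuffle_attention(np.zeros((1, 6, 2, 2)), SAParams.neutral(8, 2))

    def test_gate_strictly_shrinks_magnitudes(self, rng):
        # every gate lies in (0,1), so |out| < |in| elementwise (pre-shuffle)
        half = 2
        p = SAParams(2, *[rng.normal(size=half) for _ in range(4)],
                     shuffle=False)
        x = rng.normal(size=(3, 8, 4, 4))
        out = shuffle_attention(x, p)
        assert (np.abs(out) < np.abs(x) + 1e-12).all()


class TestEcaKernelSize:
    @pytest.mark.parametrize("c,expected", [(64, 3), (2, 1), (256, 5)])
    def test_printed_examples(self, c, expected):
        assert eca_kernel_size(c, 2, 1) == expected

    def test_even_targets_round_to_smaller_odd(self):
        # log2(c)/r + b/r = 4 exactly at c = 128: tie between 3 and 5
        assert eca_kernel_size(128, 2, 1) == 3

    @given(st.integers(min_value=1, max_value=4096))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle(self, c):
        assert eca_kernel_size(c, 2, 1) == eca_kernel_size_oracle(c, 2, 1)

    def test_non_decreasing_in_channels(self):
        ks = [eca_kernel_size(c, 2, 1) for c in range(1, 2049)]
        assert all(a <= b for a, b in zip(ks, ks[1:]))

    def test_rejects_bad_channel_count(self):
        with pytest.raises(ValueError):
            eca_kernel_size(0, 2, 1)


class TestEca:
    def test_zero_input_maps_to_zero(self):
        p = ECAParams.for_channels(4)
        assert (eca(np.zeros((1, 4, 2, 2)), p) == 0).all()

    def test_shape_preserved(self, rng):
        p = ECAParams.for_channels(8)
        x = rng.normal(size=(2, 8, 3, 5))
        assert eca(x, p).shape == x.shape

    def test_matches_loop_oracle(self, rng):
        w = rng.normal(size=3)  # k = 3 for 16 channels at r=2, b=1
        p = ECAParams.for_channels(16, conv_weights=w)
        x = rng.normal(size=(2, 16, 2, 2))
        np.testing.assert_allclose(eca(x, p), eca_oracle(x, w), atol=1e-9)

    def test_module_agrees_with_functional(self, rng):
        mod = ECA(8)
        mod.weight.data = rng.normal(size=mod.kernel_size).astype(np.float32)
        p = ECAParams.for_channels(8, conv_weights=mod.weight.data)
        x = rng.normal(size=(1, 8, 3, 3)).astype(np.float32)
        np.testing.assert_allclose(mod(Tensor(x)).data, eca(x, p), atol=1e-5)

    def test_rejects_inconsistent_kernel(self):
        p = ECAParams(r=2.0, b=1.0, kernel_size=5, conv_weights=np.zeros(5))
        with pytest.raises(ConfigurationError):
            eca(np.zeros((1, 4, 2, 2)), p)


@given(st.integers(1, 3), st.integers(1, 2), st.integers(1, 5),
       st.integers(1, 5), st.integers(0, 10_000))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_attention_preserves_shape_and_contracts(n, g, h, w, seed):
    """Property: SA and ECA keep shapes; gates strictly shrink magnitudes."""
    rng = np.random.default_rng(seed)
    c = 4 * g
    x = rng.normal(size=(n, c, h, w))
    sa = shuffle_attention(x, SAParams.neutral(c, g))
    assert sa.shape == x.shape
    assert (np.abs(sa) <= np.abs(x).max() + 1e-12).all()
    ec = eca(x, ECAParams.for_channels(c))
    assert ec.shape == x.shape
    assert (np.abs(ec) < np.abs(x) + 1e-12).all() or (x == 0).all()
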