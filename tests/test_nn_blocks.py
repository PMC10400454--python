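"""Unit tests for the neural building blocks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pestdet import nn
from pestdet.autograd import Tensor, no_grad
from pestdet.nn_blocks import (BnParams, ConvBnAct, EcaLayer, EcaSpec,
                               GhostBottleneckGE, GhostModule, GhostSpec,
                               bn_forward, conv_cost, eca_kernel_size,
                               focus_forward, ghost_cost, spp_forward,
                               ts_activation, unfocus)


class TestTsActivation:
    # expected values frozen from a 50-digit symbolic evaluation of
    # tanh(x)*log(1+exp(x))
    @pytest.mark.parametrize("x, expected", [
        (0.0, 0.0),
        (10.0, 10.000045357675957),
        (-10.0, -4.5398899029716436e-05),
        (1.0, 1.0001724264544844),
        (-1.0, -0.23857827049871949),
        (0.5, 0.45013768688171440),
    ])
    def test_values(self, x, expected):
        assert ts_activation(x) == pytest.approx(expected, rel=1e-12, abs=1e-300)

    def test_extreme_arguments_are_stable(self):
        # softplus(x) ~ x for large x, ~ e^x for very negative x
        assert ts_activation(500.0) == pytest.approx(500.0, rel=1e-6)
        assert abs(ts_activation(-500.0)) < 1e-200  # decays cleanly, not NaN
        assert np.isfinite(ts_activation(np.array([-1e4, 0.0, 1e4]))).all()

    @given(st.floats(-30, 30))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_matches_direct_formula(self, x):
        direct = np.tanh(x) * np.log1p(np.exp(-abs(x))) + np.tanh(x) * max(x, 0)
        assert ts_activation(x) == pytest.approx(direct, rel=1e-10, abs=1e-12)

    def test_asymptotes(self):
        xs = np.array([50.0, 100.0])
        assert np.allclose(ts_activation(xs) / xs, 1.0, atol=1e-6)
        assert abs(ts_activation(-60.0)) < 1e-20


class TestEcaKernelSize:
    @pytest.mark.parametrize("C, k", [(256, 5), (2, 1), (512, 5), (64, 3),
                                      (1024, 5), (4096, 7), (1, 1)])
    def test_reference_channel_counts(self, C, k):
        assert eca_kernel_size(C) == k

    def test_tie_rounds_up(self):
        # C=256: log2/2 + 1/2 = 4.5, midway between 3 and 5 -> 5
        assert eca_kernel_size(256, 2, 1) == 5

    def test_invalid_channels(self):
        with pytest.raises(ValueError):
            eca_kernel_size(0)

    @given(st.integers(1, 1 << 16))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_odd_positive_and_monotone(self, C):
        k = eca_kernel_size(C)
        assert k >= 1 and k % 2 == 1
        assert eca_kernel_size(C + 1) >= k


class TestGhostCostModel:
    def test_unit_case(self):
        spec = GhostSpec(c=1, n=1, k=1, s=1, out_h=1, out_w=1)
        assert conv_cost(spec) == 1 and ghost_cost(spec) == 1

    def test_closed_form_ratio_sweep(self):
        for c in (8, 64, 256):
            for s in (1, 2, 4):
                for k, n, h, w in [(1, 8, 4, 4), (3, 16, 7, 5)]:
                    if n % s:
                        continue
                    spec = GhostSpec(c=c, n=n, k=k, s=s, out_h=h, out_w=w)
                    ratio = conv_cost(spec) / ghost_cost(spec)
                    assert ratio == pytest.approx(s * c / (c + s - 1), rel=1e-12)

    def test_c64_s2_reference_ratio(self):
        spec = GhostSpec(c=64, n=8, k=3, s=2, out_h=5, out_w=5)
        assert conv_cost(spec) / ghost_cost(spec) == pytest.approx(128 / 65)

    def test_compression_approaches_split_factor(self):
        # the advertised compression rate ~ s as channel count grows
        for s in (2, 3, 4):
            spec = GhostSpec(c=1 << 16, n=12, k=3, s=s, out_h=2, out_w=2)
            assert conv_cost(spec) / ghost_cost(spec) == pytest.approx(s, rel=1e-3)

    def test_ghost_never_costs_more(self):
        for s in (1, 2, 3, 6):
            spec = GhostSpec(c=32, n=12, k=3, s=s, out_h=3, out_w=3)
            assert ghost_cost(spec) <= conv_cost(spec)

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            GhostSpec(c=4, n=5, k=3, s=2)
        with pytest.raises(ValueError):
            GhostSpec(c=4, n=4, k=2, s=2)
        with pytest.raises(ValueError):
            GhostSpec(c=4, n=4, k=3, s=0)


class TestFocus:
    def test_shape_contract(self):
        x = Tensor(np.zeros((1, 3, 640, 640), dtype=np.float32))
        assert focus_forward(x).shape == (1, 12, 320, 320)

    def test_constant_image_stays_constant(self):
        x = Tensor(np.full((2, 3, 8, 8), 3.25, dtype=np.float32))
        assert np.all(focus_forward(x).data == 3.25)

    def test_round_trip_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 5, 12, 10)).astype(np.float32)
        y = focus_forward(Tensor(x)).data
        assert np.array_equal(unfocus(y), x)

    def test_odd_dims_rejected(self):
        with pytest.raises(ValueError):
            focus_forward(Tensor(np.zeros((1, 1, 7, 8), dtype=np.float32)))


class TestSpp:
    def test_shape_and_constant(self):
        x = Tensor(np.full((1, 6, 20, 20), 2.0, dtype=np.float32))
        y = spp_forward(x)
        assert y.shape == (1, 24, 20, 20)
        assert np.all(y.data == 2.0)

    def test_single_bright_pixel_dilates_to_kernel_blocks(self):
        x = np.zeros((1, 1, 15, 15), dtype=np.float32)
        x[0, 0, 7, 7] = 1.0
        y = spp_forward(Tensor(x), pool_sizes=(5,)).data
        pooled = y[0, 1]
        expect = np.zeros((15, 15))
        expect[5:10, 5:10] = 1.0  # 5x5 max-pool spreads the peak
        assert np.array_equal(pooled, expect)


class TestBnForward:
    def test_centered_input_returns_beta(self):
        p = BnParams(gamma=[2.0, 3.0], beta=[0.5, -1.0],
                     batch_mean=[1.0, 2.0], batch_std=[1.0, 1.0])
        out = bn_forward(np.array([[1.0], [2.0]]), p)
        assert np.allclose(out[:, 0], [0.5, -1.0])

    def test_standardization(self):
        rng = np.random.default_rng(1)
        z = rng.normal(3.0, 2.0, (1, 10000))
        p = BnParams(gamma=[1.0], beta=[0.0], batch_mean=[z.mean()],
                     batch_std=[z.std()], eps=1e-12)
        out = bn_forward(z, p)
        assert abs(out.mean()) < 1e-9
        assert out.std() == pytest.approx(1.0, abs=1e-5)

    def test_zero_scale_erases_input(self):
        p = BnParams(gamma=[0.0], beta=[7.0], batch_mean=[0.0], batch_std=[1.0])
        out = bn_forward(np.array([[-5.0, 0.0, 100.0]]), p)
        assert np.all(out == 7.0)

    def test_invalid_eps(self):
        with pytest.raises(ValueError):
            BnParams(gamma=[1.0], beta=[0.0], batch_mean=[0.0],
                     batch_std=[1.0], eps=0.0)


class TestEca:
    def test_identity_gate(self):
        # huge positive weights + positive descriptor -> sigmoid saturates at 1
        eca = EcaLayer(EcaSpec(4, kernel=1))
        eca.weight.data[:] = 1e4
        x = Tensor(np.abs(np.random.default_rng(0).standard_normal(
            (2, 4, 5, 5))).astype(np.float32) + 0.1)
        with no_grad():
            y = eca(x)
        assert np.allclose(y.data, x.data, atol=1e-6)

    def test_k1_gate_is_sigmoid_of_scaled_mean(self):
        eca = EcaLayer(EcaSpec(3, kernel=1))
        w = 0.7
        eca.weight.data[:] = w
        means = np.array([0.5, -1.0, 2.0], dtype=np.float32)
        x = np.broadcast_to(means[None, :, None, None], (1, 3, 4, 4)).copy()
        with no_grad():
            y = eca(Tensor(x))
        gate = 1.0 / (1.0 + np.exp(-w * means))
        assert np.allclose(y.data[0, :, 0, 0], means * gate, atol=1e-6)

    def test_output_shape_matches_input(self):
        eca = EcaLayer(EcaSpec(16))
        x = Tensor(np.random.default_rng(2).standard_normal(
            (3, 16, 7, 9)).astype(np.float32))
        with no_grad():
            assert eca(x).shape == x.shape

    def test_channel_mismatch_rejected(self):
        eca = EcaLayer(EcaSpec(8))
        with pytest.raises(ValueError):
            eca(Tensor(np.zeros((1, 4, 2, 2), dtype=np.float32)))


def _neutral_bns(module):
    for m in module.modules():
        if isinstance(m, nn.BatchNorm2d):
            m.gamma.data[:] = 1.0
            m.beta.data[:] = 0.0
            m.running_mean[:] = 0.0
            m.running_var[:] = 1.0 - m.eps


class TestGhostModule:
    def test_s1_degenerates_to_plain_conv(self):
        g = GhostModule(3, 4, k=3, s=1, act="none")
        assert len(g.cheap) == 0
        x = Tensor(np.random.default_rng(0).standard_normal(
            (1, 3, 6, 6)).astype(np.float32))
        g.eval()
        with no_grad():
            ya = g(x)
            yb = g.primary(x)
        assert np.array_equal(ya.data, yb.data)

    def test_channel_bookkeeping(self):
        g = GhostModule(6, 4, s=2)
        x = Tensor(np.zeros((2, 6, 8, 8), dtype=np.float32))
        g.eval()
        with no_grad():
            y = g(x)
        assert y.shape == (2, 4, 8, 8)
        assert g.primary.conv.out_channels == 2 and len(g.cheap) == 1

    def test_identity_cheap_kernels_duplicate_real_channels(self):
        g = GhostModule(3, 8, k=1, s=2, act="none")
        _neutral_bns(g)
        dw = g.cheap[0].conv
        dw.weight.data[:] = 0.0
        dw.weight.data[:, 0, 1, 1] = 1.0  # centered identity depthwise kernel
        g.eval()
        x = Tensor(np.random.default_rng(1).standard_normal(
            (1, 3, 5, 5)).astype(np.float32))
        with no_grad():
            y = g(x).data
        assert np.allclose(y[:, :4], y[:, 4:], atol=1e-5)

    def test_indivisible_split_rejected(self):
        with pytest.raises(ValueError):
            GhostModule(3, 5, s=2)


class TestGhostBottleneckGE:
    def test_zero_trunk_returns_shortcut(self):
        blk = GhostBottleneckGE(6, 6, stride=1)
        _neutral_bns(blk)
        for mod in blk.ghost2.modules():
            if isinstance(mod, nn.Conv2d):
                mod.weight.data[:] = 0.0
        blk.eval()
        x = Tensor(np.random.default_rng(0).standard_normal(
            (1, 6, 8, 8)).astype(np.float32))
        with no_grad():
            y = blk(x)
        assert np.allclose(y.data, x.data, atol=1e-6)

    def test_stride2_halves_spatial_dims(self):
        blk = GhostBottleneckGE(4, 8, stride=2)
        blk.eval()
        x = Tensor(np.zeros((1, 4, 16, 16), dtype=np.float32))
        with no_grad():
            assert blk(x).shape == (1, 8, 8, 8)

    def test_saturated_eca_equals_eca_free_composition(self):
        rng = np.random.default_rng(3)
        blk = GhostBottleneckGE(5, 5, stride=1, act="none", rng=rng)
        blk.eval()
        blk.eca.weight.data[:] = 1e4
        # positive mid-features guarantee a positive channel descriptor
        for g in (blk.ghost1, blk.ghost2):
            pass
        x = Tensor(np.abs(rng.standard_normal((1, 5, 6, 6))).astype(np.float32))
        for m in blk.ghost1.modules():
            if isinstance(m, nn.Conv2d):
                m.weight.data = np.abs(m.weight.data)
        with no_grad():
            with_eca = blk(x).data
            eca = blk.eca
            blk.eca = nn.Identity()
            without = blk(x).data
            blk.eca = eca
        assert np.allclose(with_eca, without, atol=1e-5)

    def test_bad_stride_rejected(self):
        with pytest.raises(ValueError):
            GhostBottleneckGE(4, 4, stride=3)


class TestConvBnAct:
    def test_cbs_and_cbt_share_parameter_count(self):
        a = ConvBnAct(3, 8, 3, act="silu")
        b = ConvBnAct(3, 8, 3, act="ts")
        assert (sum(p.size for p in a.parameters())
                == sum(p.size for p in b.parameters()))
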