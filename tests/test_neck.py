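import numpy as np
import pytest

from safi.backbone import FeaturePyramid
from safi.blocks import Bottleneck, C2f
from safi.neck import (ELCConv, BottleneckELC, C2fELC, ElcCostSpec, ElcSpec,
                       PanNeck, elc_cost)
from safi.nn import Tensor, count_macs, no_grad


def fwd(m, x):
    with no_grad():
        return m(x)


class TestElcCost:
    def test_unit_example(self):
        c1, c2, _ = elc_cost(ElcCostSpec(k=3, c=1, n=1, x=1, y=1))
        assert c1 == 144          # 9 * 4 * 4
        assert c2 == 84           # 1 + 9 + 25 + 49

    def test_printed_ratio(self):
        for c, n, x, y in [(1, 1, 1, 1), (16, 16, 40, 40), (3, 5, 7, 11)]:
            _, _, ratio = elc_cost(ElcCostSpec(k=3, c=c, n=n, x=x, y=y))
            assert ratio == pytest.approx(144 / 84, rel=1e-12)
            assert round(ratio, 1) == 1.7

    def test_ratio_constant_12_over_7(self, rng):
        for _ in range(20):
            spec = ElcCostSpec(3, *map(int, rng.integers(1, 64, size=4)))
            assert elc_cost(spec)[2] == pytest.approx(12 / 7, rel=1e-12)

    def test_linearity_in_x(self):
        s1 = ElcCostSpec(k=3, c=4, n=4, x=10, y=10)
        s2 = ElcCostSpec(k=3, c=4, n=4, x=20, y=10)
        c1a, c2a, ra = elc_cost(s1)
        c1b, c2b, rb = elc_cost(s2)
        assert c1b == 2 * c1a and c2b == 2 * c2a and ra == rb

    def test_closed_form_matches_enumeration_50_specs(self, rng):
        # independent oracle: enumerate multiply-accumulates per output
        # element and kernel tap, exactly
        for _ in range(50):
            k, c, n = map(int, rng.integers(1, 8, size=3))
            x, y = map(int, rng.integers(1, 12, size=2))
            spec = ElcCostSpec(k=k, c=c, n=n, x=x, y=y)
            std = sum(1 for _ in range(k * k)) * (4 * c) * (4 * n) * x * y
            grouped = sum(kk * kk * c * n * x * y for kk in (1, 3, 5, 7))
            c1, c2, _ = elc_cost(spec)
            assert c1 == std and c2 == grouped

    def test_pointwise_variant_included(self):
        spec = ElcCostSpec(k=3, c=2, n=2, x=5, y=5)
        _, c2_plain, _ = elc_cost(spec)
        _, c2_pw, _ = elc_cost(spec, include_pointwise=True)
        assert c2_pw == c2_plain + 4 * 2 * 4 * 2 * 25

    def test_validation(self):
        with pytest.raises(ValueError):
            ElcCostSpec(k=0, c=1, n=1, x=1, y=1)


class TestElcConv:
    def test_shape_conservation(self, rng):
        m = ELCConv(64, rng=rng).eval()
        y = fwd(m, Tensor(rng.normal(size=(1, 64, 40, 40)).astype(np.float32)))
        assert y.shape == (1, 64, 40, 40)

    def test_channels_not_divisible_rejected(self):
        with pytest.raises(ValueError, match="divisible by 4"):
            ElcSpec(30)

    def test_measured_macs_match_cost_law(self, rng):
        # c = n = 16 (64 channels / 4 groups), 40x40 maps
        m = ELCConv(64, rng=rng).eval()
        with no_grad(), count_macs() as tally:
            m(Tensor(np.zeros((1, 64, 40, 40), dtype=np.float32)))
        spec = ElcCostSpec(k=3, c=16, n=16, x=40, y=40)
        _, c2, _ = elc_cost(spec, include_pointwise=True)
        assert tally.macs == c2

    def test_spatially_constant_input(self, rng):
        m = ELCConv(8, rng=rng).eval()
        x = np.full((1, 8, 16, 16), 3.5, dtype=np.float32)
        y = fwd(m, Tensor(x)).data
        interior = y[:, :, 4:-4, 4:-4]
        assert np.allclose(interior, interior[:, :, :1, :1], atol=1e-4)

    def test_wrong_channels_at_forward(self, rng):
        m = ELCConv(16, rng=rng)
        with pytest.raises(ValueError, match="ELC configured"):
            fwd(m, Tensor(np.zeros((1, 8, 4, 4), dtype=np.float32)))


class TestBottleneckELC:
    def test_shape(self, rng):
        m = BottleneckELC(128, 128, rng=rng).eval()
        y = fwd(m, Tensor(rng.normal(size=(1, 128, 20, 20)).astype(np.float32)))
        assert y.shape == (1, 128, 20, 20)

    def test_residual_identity_contribution(self, rng):
        m = BottleneckELC(16, 16, shortcut=True, rng=rng).eval()
        # zero the ELC mixing conv: the ELC path contributes exactly zero
        m.cv2.mix.conv.weight.data[:] = 0.0
        m.cv2.mix.bn.bias.data[:] = 0.0
        x = Tensor(rng.normal(size=(1, 16, 8, 8)).astype(np.float32))
        y = fwd(m, x)
        assert np.allclose(y.data, x.data, atol=1e-5)

    def test_fewer_params_than_stock(self, rng):
        for c in (32, 64, 128):
            elc = BottleneckELC(c, c, rng=rng).num_parameters()
            stock = Bottleneck(c, c, rng=rng).num_parameters()
            assert elc < stock
            # per-layer arithmetic: saving = 9c^2+2c - (84/16 c^2 + 2c + c^2 + 2c)
            assert stock - elc == int(2.75 * c * c - 2 * c)


class TestC2fELC:
    def test_same_shape_as_stock(self, rng):
        x = Tensor(rng.normal(size=(2, 96, 16, 16)).astype(np.float32))
        a = fwd(C2f(96, 64, 1, rng=rng).eval(), x)
        b = fwd(C2fELC(96, 64, 1, rng=rng).eval(), x)
        assert a.shape == b.shape

    def test_zero_fuse_conv_zeroes_output(self, rng):
        m = C2fELC(32, 32, 1, rng=rng).eval()
        m.cv2.conv.weight.data[:] = 0.0
        m.cv2.bn.bias.data[:] = 0.0
        y = fwd(m, Tensor(rng.normal(size=(1, 32, 8, 8)).astype(np.float32)))
        assert np.allclose(y.data, 0.0, atol=1e-6)


class TestPanNeck:
    @pytest.mark.parametrize("use_elc", [False, True])
    def test_strides_and_channels(self, rng, use_elc):
        neck = PanNeck((64, 128, 256), (64, 128, 256), use_elc=use_elc, rng=rng).eval()
        pyr = FeaturePyramid(
            Tensor(np.zeros((1, 64, 40, 40), dtype=np.float32)),
            Tensor(np.zeros((1, 128, 20, 20), dtype=np.float32)),
            Tensor(np.zeros((1, 256, 10, 10), dtype=np.float32)))
        with no_grad():
            out = neck(pyr)
        assert out.p3.shape == (1, 64, 40, 40)
        assert out.p4.shape == (1, 128, 20, 20)
        assert out.p5.shape == (1, 256, 10, 10)

    def test_swap_preserves_all_shapes(self, rng):
        """Replacing C2f with C2f_ELC never changes inter-module shapes."""
        pyr = FeaturePyramid(
            Tensor(np.zeros((1, 32, 24, 24), dtype=np.float32)),
            Tensor(np.zeros((1, 64, 12, 12), dtype=np.float32)),
            Tensor(np.zeros((1, 128, 6, 6), dtype=np.float32)))
        with no_grad():
            a = PanNeck((32, 64, 128), (64, 112, 224), use_elc=False, rng=rng).eval()(pyr)
            b = PanNeck((32, 64, 128), (64, 112, 224), use_elc=True, rng=rng).eval()(pyr)
        for pa, pb in zip(a.as_list(), b.as_list()):
            assert pa.shape == pb.shape

    def test_channel_mismatch_raises(self, rng):
        neck = PanNeck((64, 128, 256), (64, 128, 256), rng=rng)
        pyr = FeaturePyramid(
            Tensor(np.zeros((1, 32, 8, 8), dtype=np.float32)),
            Tensor(np.zeros((1, 64, 4, 4), dtype=np.float32)),
            Tensor(np.zeros((1, 128, 2, 2), dtype=np.float32)))
        with pytest.raises(ValueError, match="neck expects channels"):
            with no_grad():
                neck(pyr)
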