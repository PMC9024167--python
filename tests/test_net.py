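"""Autodiff correctness and network building-block contracts."""

import numpy as np
import pytest

from drdseg.metrics import dice
from drdseg.net import (
    Conv,
    ContextModule,
    GroupNorm,
    NetConfig,
    ResidualUnit,
    Tensor,
    build_network,
    load_checkpoint,
    maxpool2,
    save_checkpoint,
    stack_residuals,
    train_network,
    upsample2,
)


def _numeric_grad(fn, x, eps=1e-6):
    g = np.zeros_like(x)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn(x)
        flat[i] = orig - eps
        lo = fn(x)
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g


class TestAutodiff:
    def test_gradient_matches_finite_differences(self):
        """End-to-end gradcheck through conv, GN, ReLU, pool, upsample, sigmoid."""
        rng = np.random.default_rng(0)
        x0 = rng.random((1, 2, 8, 8))
        conv = Conv(2, 4, 3, rng=rng)
        gn = GroupNorm(4, 2)
        head = Conv(4, 1, 1, rng=rng)

        def forward(arr):
            t = Tensor(arr)
            h = gn(conv(t)).relu()
            h = upsample2(maxpool2(h))
            return float(head(h).sigmoid().sum().data)

        t = Tensor(x0.copy(), requires_grad=True)
        h = gn(conv(t)).relu()
        h = upsample2(maxpool2(h))
        out = head(h).sigmoid().sum()
        out.backward()
        want = _numeric_grad(forward, x0.copy())
        np.testing.assert_allclose(t.grad, want, atol=1e-6)

    def test_weight_gradients_match_finite_differences(self):
        rng = np.random.default_rng(1)
        x = Tensor(rng.random((2, 3, 6, 6)))
        conv = Conv(3, 2, 3, dilation=2, rng=rng)

        def forward(w):
            conv.weight.data = w
            return float((conv(x) * conv(x)).sum().data)

        w0 = conv.weight.data.copy()
        out = (conv(x) * conv(x)).sum()
        out.backward()
        want = _numeric_grad(forward, w0.copy())
        conv.weight.data = w0
        np.testing.assert_allclose(conv.weight.grad, want, atol=1e-5)


class TestResidualUnit:
    def test_zeroed_branch_is_exact_identity(self):
        unit = ResidualUnit(8, 8, zero_init=True)
        x = Tensor(np.random.default_rng(2).random((2, 8, 16, 16)))
        np.testing.assert_array_equal(unit(x).data, x.data)

    def test_output_decomposes_into_shortcut_plus_branch(self):
        unit = ResidualUnit(4, 8, gn_groups=4, shortcut="project", rng=np.random.default_rng(3))
        x = Tensor(np.random.default_rng(4).random((1, 4, 12, 12)))
        total = unit(x).data
        parts = unit.shortcut_map(x).data + unit.branch(x).data
        np.testing.assert_allclose(total, parts, atol=1e-6)

    def test_channel_change_without_projection_rejected(self):
        with pytest.raises(ValueError):
            ResidualUnit(4, 8)


class TestStackResiduals:
    def test_zero_branches_preserve_input(self):
        units = [ResidualUnit(4, 4, gn_groups=4, zero_init=True) for _ in range(3)]
        x = Tensor(np.random.default_rng(5).random((1, 4, 8, 8)))
        np.testing.assert_array_equal(stack_residuals(x, units).data, x.data)

    def test_telescoped_sum_equality(self):
        """b_N = b_n + sum_i F(b_i, W_i) accumulated independently."""
        rng = np.random.default_rng(6)
        units = [ResidualUnit(4, 4, gn_groups=4, rng=rng) for _ in range(3)]
        x = Tensor(rng.random((1, 4, 8, 8)))
        stacked = stack_residuals(x, units).data
        b = x
        total = x.data.copy()
        for unit in units:
            total = total + unit.branch(b).data
            b = unit(b)
        np.testing.assert_allclose(stacked, total, atol=1e-9)

    def test_single_unit_matches_residual_unit(self):
        unit = ResidualUnit(4, 4, gn_groups=4, rng=np.random.default_rng(7))
        x = Tensor(np.random.default_rng(8).random((1, 4, 8, 8)))
        np.testing.assert_array_equal(stack_residuals(x, [unit]).data, unit(x).data)


class TestContextModule:
    def test_preserves_shape(self):
        cm = ContextModule(8, rates=(3, 5, 7, 9), rng=np.random.default_rng(9))
        x = Tensor(np.random.default_rng(10).random((2, 8, 16, 16)))
        assert cm(x).shape == (2, 8, 16, 16)

    def test_zero_weights_give_zero_output(self):
        cm = ContextModule(8, zero_init=True, bias=False)
        x = Tensor(np.random.default_rng(11).random((1, 8, 16, 16)))
        out = cm(x)
        assert out.shape == x.shape
        assert np.all(out.data == 0.0)

    @pytest.mark.parametrize("branch,rate", list(enumerate((3, 5, 7, 9))))
    def test_receptive_field_is_2r_plus_1(self, branch, rate):
        """Gradient footprint of one output voxel spans 2r+1 voxels per axis."""
        cm = ContextModule(8, rng=np.random.default_rng(12))
        x = Tensor(np.random.default_rng(13).random((1, 8, 40, 40)), requires_grad=True)
        out = cm(x)
        g = np.zeros_like(out.data)
        g[0, branch * 2, 20, 20] = 1.0
        out.backward(g)
        support = np.nonzero(np.abs(x.grad).sum(axis=(0, 1)))
        for ax in support:
            assert ax.max() - ax.min() + 1 == 2 * rate + 1

    def test_translation_equivariance_in_interior(self):
        cm = ContextModule(4, rates=(1, 2, 3, 4), rng=np.random.default_rng(14))
        base = np.random.default_rng(15).random((1, 4, 40, 40))
        shifted = np.roll(base, 2, axis=2)
        out_a = cm(Tensor(base)).data
        out_b = cm(Tensor(shifted)).data
        # compare away from the wrap-around/padding boundary
        np.testing.assert_allclose(out_a[:, :, 10:20, 10:30], out_b[:, :, 12:22, 10:30], atol=1e-10)

    def test_rejects_bad_channels_or_rates(self):
        with pytest.raises(ValueError):
            ContextModule(6)
        with pytest.raises(ValueError):
            ContextModule(8, rates=(1, 2, 3))


class TestNetwork:
    def test_untrained_output_is_probability_map(self):
        net = build_network(NetConfig(depth=3, base_channels=16), seed=0)
        img = np.random.default_rng(16).random((84, 84))
        prob = net.predict(img)
        assert prob.shape == (84, 84)
        assert np.all(np.isfinite(prob)) and prob.min() > 0.0 and prob.max() < 1.0

    def test_rejects_indivisible_spatial_dims(self):
        net = build_network(NetConfig(depth=3, base_channels=16))
        with pytest.raises(ValueError):
            net.predict(np.zeros((50, 50)))

    def test_parameter_count_independent_of_input_size(self):
        net = build_network(NetConfig(depth=2, base_channels=8))
        n0 = net.n_parameters()
        net.predict(np.zeros((16, 16)))
        net.predict(np.zeros((32, 32)))
        assert net.n_parameters() == n0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetConfig(dilation_rates=(1, 2, 3))
        with pytest.raises(ValueError):
            NetConfig(base_channels=12, gn_groups=8)

    def test_overfit_small_phantom_batch(self, phantom_batch):
        """Gradients flow through residual and context blocks: training Dice >= 0.9."""
        images, masks = phantom_batch
        net = build_network(NetConfig(depth=2, base_channels=8), seed=0)
        history = train_network(net, images, masks, steps=120, lr=3e-3, log_every=10)
        assert max(h["dice"] for h in history) >= 0.9

    def test_checkpoint_round_trip(self, tmp_path):
        net = build_network(NetConfig(depth=2, base_channels=8), seed=1)
        img = np.random.default_rng(17).random((32, 32))
        before = net.predict(img)
        path = tmp_path / "model.npz"
        save_checkpoint(net, path)
        restored = load_checkpoint(path)
        np.testing.assert_array_equal(restored.predict(img), before)

    def test_3d_mode_smoke(self):
        net = build_network(NetConfig(depth=2, base_channels=8, use_3d=True), seed=2)
        vol = np.random.default_rng(18).random((16, 16, 16))
        prob = net.predict(vol)
        assert prob.shape == (16, 16, 16)
        assert 0.0 < prob.min() and prob.max() < 1.0

    def test_deep_supervision_trains(self, phantom_batch):
        images, masks = phantom_batch
        net = build_network(
            NetConfig(depth=3, base_channels=8, deep_supervision=True), seed=3
        )
        history = train_network(net, images[:2], masks[:2], steps=5, log_every=5)
        assert np.isfinite(history[-1]["loss"])
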