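"""Behavioural contracts of the PDCM, channel attention and residual blocks."""

import numpy as np
import pytest

from pdcnet.autodiff import Module, Tensor
from pdcnet.blocks import (
    BasicConvBlock,
    BlockConfig,
    ChannelAttention,
    ConvBNReLU,
    PDCM,
    Residual,
    dropblock,
)


def zero_all_conv_params(module):
    for _, p in module.named_parameters():
        p.data = np.zeros_like(p.data)


class TestBlockConfig:
    def test_rejects_non_increasing_dilations(self):
        with pytest.raises(ValueError, match="dilation"):
            BlockConfig(in_channels=4, out_channels=4, dilation_rates=(4, 2, 6))

    def test_rejects_nonpositive_dilations(self):
        with pytest.raises(ValueError, match="dilation"):
            BlockConfig(in_channels=4, out_channels=4, dilation_rates=(0, 2, 4))


class TestChannelAttention:
    def test_zero_input_zero_convs_gives_zero_output(self):
        cam = ChannelAttention(4, np.random.default_rng(0))
        zero_all_conv_params(cam)
        out = cam(Tensor(np.zeros((1, 4, 8, 8))))
        assert np.all(out.data == 0.0)

    def test_zero_convs_gate_is_exactly_half(self):
        cam = ChannelAttention(4, np.random.default_rng(0))
        zero_all_conv_params(cam)
        x = np.random.default_rng(1).normal(size=(2, 4, 6, 6))
        out = cam(Tensor(x))
        assert np.allclose(out.data, 0.5 * x, atol=1e-7)

    @pytest.mark.parametrize("c", [1, 3, 16])
    @pytest.mark.parametrize("hw", [8, 16])
    def test_output_shape_matches_input(self, c, hw):
        cam = ChannelAttention(c, np.random.default_rng(c))
        x = np.random.default_rng(hw).normal(size=(2, c, hw, hw))
        assert cam(Tensor(x)).shape == (2, c, hw, hw)

    def test_attenuates_nonnegative_input(self):
        # each channel weight is a sigmoid output in (0,1)
        cam = ChannelAttention(8, np.random.default_rng(2))
        x = np.abs(np.random.default_rng(3).normal(size=(2, 8, 8, 8)))
        out = cam(Tensor(x))
        assert np.all(out.data <= x + 1e-9)
        assert np.all(out.data >= 0.0)

    def test_rejects_zero_channels(self):
        with pytest.raises(ValueError):
            ChannelAttention(0, np.random.default_rng(0))


class TestPDCM:
    def cfg(self, **kw):
        base = dict(in_channels=3, out_channels=4, dropblock_rate=0.0)
        base.update(kw)
        return BlockConfig(**base)

    def test_zero_weights_give_zero_output(self):
        block = PDCM(self.cfg(), np.random.default_rng(0))
        zero_all_conv_params(block)
        block.eval()
        out = block(Tensor(np.random.default_rng(1).normal(size=(1, 3, 16, 16))))
        assert np.allclose(out.data, 0.0)

    def test_output_channels_equal_out_channels_for_both_fusion_modes(self):
        for prev in (True, False):
            block = PDCM(self.cfg(use_previous_branch=prev), np.random.default_rng(1))
            block.eval()
            out = block(Tensor(np.zeros((2, 3, 8, 8))))
            assert out.shape == (2, 4, 8, 8)

    def test_spatial_size_preserved_at_all_dilations(self):
        block = PDCM(self.cfg(), np.random.default_rng(2))
        block.eval()
        for hw in (8, 16, 32):
            assert block(Tensor(np.zeros((1, 3, hw, hw)))).shape[2:] == (hw, hw)

    def test_branch_receptive_field_extents_follow_dilation(self):
        # impulse response extents: 1x1 -> 1; 3x3 at d=2,4,6 -> 5, 9, 13
        from pdcnet.network import _probe_extents

        bc = BlockConfig(in_channels=1, out_channels=1, use_previous_branch=False,
                         cam_reduction=1, dropblock_rate=0.0)
        block = PDCM(bc, np.random.default_rng(3))
        extents = _probe_extents(block)
        assert extents[:4] == [1, 5, 9, 13]

    def test_independent_branches_read_only_the_reduced_input(self):
        # without previous-branch fusion each dilated branch is a function of
        # F_in' alone, so recomputing it in isolation matches the module
        block = PDCM(self.cfg(use_previous_branch=False), np.random.default_rng(4))
        block.eval()
        x = Tensor(np.random.default_rng(5).normal(size=(1, 3, 12, 12)))
        _, branches = block(x, return_branches=True)
        f_in = block.reduce(x)
        for k, conv in enumerate(block.dilated):
            standalone = conv(f_in)
            assert np.allclose(branches[k + 1].data, standalone.data, atol=1e-6)

    def test_previous_branch_fusion_changes_dataflow_not_parameters(self):
        a = PDCM(self.cfg(use_previous_branch=True), np.random.default_rng(6))
        b = PDCM(self.cfg(use_previous_branch=False), np.random.default_rng(6))
        assert a.num_parameters() == b.num_parameters()
        x = Tensor(np.random.default_rng(7).normal(size=(1, 3, 8, 8)))
        a.eval(), b.eval()
        assert not np.allclose(a(x).data, b(x).data)

    def test_parameter_count_ordering(self):
        full = PDCM(self.cfg(), np.random.default_rng(8)).num_parameters()
        no_cam = PDCM(self.cfg(use_cam=False), np.random.default_rng(8)).num_parameters()
        plain = ConvBNReLU(4, 4, 3, np.random.default_rng(8)).num_parameters()
        assert full > no_cam > plain

    def test_channel_mismatch_raises(self):
        block = PDCM(self.cfg(), np.random.default_rng(9))
        with pytest.raises(ValueError, match="channels"):
            block(Tensor(np.zeros((1, 5, 8, 8))))


class _Identity(Module):
    def forward(self, x):
        return x


class TestResidual:
    def test_zero_main_path_is_identity_shortcut(self):
        main = ConvBNReLU(3, 3, 3, np.random.default_rng(0))
        zero_all_conv_params(main)
        res = Residual(main, 3, 3, np.random.default_rng(1))
        res.eval()
        x = np.random.default_rng(2).normal(size=(1, 3, 8, 8))
        assert np.allclose(res(Tensor(x)).data, x, atol=1e-7)

    def test_identity_main_path_doubles_input(self):
        res = Residual(_Identity(), 3, 3, np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(1, 3, 4, 4))
        assert np.allclose(res(Tensor(x)).data, 2 * x)

    def test_projection_added_only_on_channel_change(self):
        assert Residual(_Identity(), 3, 3, np.random.default_rng(0)).proj is None
        r = Residual(ConvBNReLU(3, 6, 3, np.random.default_rng(0)), 3, 6,
                     np.random.default_rng(1))
        assert r.proj is not None
        assert r.proj.weight.data.shape == (6, 3, 1, 1)
        assert r.proj.bias is None

    def test_gradient_passes_through_shortcut_unchanged(self):
        main = ConvBNReLU(2, 2, 3, np.random.default_rng(0))
        zero_all_conv_params(main)
        res = Residual(main, 2, 2, np.random.default_rng(1))
        res.eval()
        x = Tensor(np.random.default_rng(2).normal(size=(1, 2, 6, 6)),
                   requires_grad=True)
        out = res(x)
        upstream = np.random.default_rng(3).normal(size=out.shape)
        out.backward(upstream)
        # main path is dead (zero weights, ReLU off) so dL/dx is the shortcut
        assert np.allclose(x.grad, upstream, atol=1e-8)


class TestDropBlock:
    def test_identity_in_eval_mode_and_at_zero_rate(self):
        x = Tensor(np.ones((2, 3, 16, 16)))
        rng = np.random.default_rng(0)
        assert dropblock(x, 0.1, 5, rng, training=False) is x
        assert dropblock(x, 0.0, 5, rng, training=True) is x

    def test_drops_contiguous_blocks_and_rescales(self):
        rng = np.random.default_rng(1)
        x = Tensor(np.ones((4, 8, 32, 32)))
        out = dropblock(x, 0.2, 5, rng, training=True)
        dropped = np.mean(out.data == 0.0)
        assert 0.05 < dropped < 0.5  # roughly the requested rate
        # kept activations are rescaled to preserve the expected sum
        assert out.data.sum() == pytest.approx(x.data.sum(), rel=1e-5)

    def test_block_size_clamped_to_small_maps(self):
        rng = np.random.default_rng(2)
        x = Tensor(np.ones((1, 2, 4, 4)))
        out = dropblock(x, 0.3, 7, rng, training=True)  # block > map size
        assert out.shape == x.shape

    def test_basic_conv_block_applies_dropblock_only_in_training(self):
        blk = BasicConvBlock(1, 2, np.random.default_rng(0), dropblock_rate=0.5,
                             dropblock_seed=1)
        x = Tensor(np.random.default_rng(1).uniform(0.5, 1.0, size=(1, 1, 16, 16)))
        blk.eval()
        e1, e2 = blk(x).data, blk(x).data
        assert np.array_equal(e1, e2)  # eval is deterministic, no dropping
        blk.train()
        t1 = blk(x).data
        assert (t1 == 0).mean() > (e1 == 0).mean()
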