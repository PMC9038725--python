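"""Architecture contracts: block shapes, attention algebra, composition."""

import numpy as np
import pytest

from darunet.autodiff import Tensor
from darunet.config import LayerHyperParams, NetworkConfig
from darunet.model import (AttentionGate, DecoderBlock, DoubleNet,
                           EncoderBlock, InvalidShapeError, OutputHead,
                           ResidualBlock, ResidualStack, assemble_double_net,
                           build_single_net, count_parameters)

HP = LayerHyperParams()


def _rng():
    return np.random.default_rng(0)


def _identity_bn(bn):
    bn.gamma.data[:] = 1.0
    bn.beta.data[:] = 0.0
    bn.running_mean[:] = 0.0
    bn.running_var[:] = 1.0 - bn.eps  # so 1/sqrt(rv + eps) == 1 exactly


class TestEncoderBlock:
    @pytest.mark.parametrize("shape,filters,expected", [
        ((1, 64, 64, 1), 20, (1, 32, 32, 20)),
        ((1, 10, 10, 3), 5, (1, 5, 5, 5)),
        ((2, 15, 9, 4), 8, (2, 8, 5, 8)),  # ceil(d/2) on odd dims
    ])
    def test_halves_spatial_dims(self, shape, filters, expected):
        block = EncoderBlock(shape[-1], filters, HP, _rng())
        assert block(Tensor(np.zeros(shape))).shape == expected

    def test_zeroed_weights_identity_bn_give_zero_output(self):
        block = EncoderBlock(1, 4, HP, _rng()).eval()
        block.conv.weight.data[:] = 0.0
        block.conv.bias.data[:] = 0.0
        _identity_bn(block.bn)
        out = block(Tensor(np.random.default_rng(1).normal(size=(1, 8, 8, 1))))
        assert np.all(out.data == 0.0)

    def test_rejects_bad_rank(self):
        block = EncoderBlock(1, 4, HP, _rng())
        with pytest.raises(InvalidShapeError):
            block(Tensor(np.zeros((8, 8))))


class TestDecoderBlock:
    def test_doubles_dims_and_sums_channels(self):
        block = DecoderBlock(320, 160, HP, _rng()).eval()
        x = Tensor(np.random.default_rng(1).normal(size=(1, 15, 10, 320)))
        skip = Tensor(np.zeros((1, 30, 20, 160)))
        assert block(x, [skip]).shape == (1, 30, 20, 320)

    def test_inference_is_deterministic(self):
        block = DecoderBlock(8, 4, HP, _rng()).eval()
        x = Tensor(np.random.default_rng(2).normal(size=(1, 4, 4, 8)))
        skip = Tensor(np.random.default_rng(3).normal(size=(1, 8, 8, 2)))
        a = block(x, [skip]).data
        b = block(x, [skip]).data
        assert np.array_equal(a, b)

    def test_output_is_nonnegative(self):
        block = DecoderBlock(8, 4, HP, _rng()).eval()
        x = Tensor(np.random.default_rng(4).normal(size=(1, 4, 4, 8)))
        skip = Tensor(np.random.default_rng(5).normal(size=(1, 8, 8, 3)))
        assert block(x, [skip]).data.min() >= 0.0

    def test_skip_spatial_mismatch_raises(self):
        block = DecoderBlock(8, 4, HP, _rng()).eval()
        x = Tensor(np.zeros((1, 4, 4, 8)))
        with pytest.raises(InvalidShapeError):
            block(x, [Tensor(np.zeros((1, 9, 8, 2)))])


class TestResidualBlock:
    def _zeroed(self, filters=6):
        block = ResidualBlock(filters, HP, _rng()).eval()
        for conv in (block.conv1, block.conv2):
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
        for bn in (block.bn1, block.bn2):
            _identity_bn(bn)
        return block

    def test_zeroed_branch_is_exact_identity(self):
        block = self._zeroed()
        x = np.random.default_rng(6).normal(size=(1, 5, 7, 6))
        assert np.array_equal(block(Tensor(x)).data, x)

    def test_preserves_shape(self):
        block = ResidualBlock(320, HP, _rng()).eval()
        x = Tensor(np.random.default_rng(7).normal(size=(1, 15, 10, 320)))
        assert block(x).shape == (1, 15, 10, 320)

    def test_output_minus_input_equals_branch(self):
        block = ResidualBlock(6, HP, _rng()).eval()
        x = Tensor(np.random.default_rng(8).normal(size=(1, 4, 4, 6)))
        out = block(x).data
        branch = block.branch(x).data
        assert np.allclose(out - x.data, branch)

    def test_channel_mismatch_raises(self):
        with pytest.raises(InvalidShapeError):
            ResidualBlock(6, HP, _rng())(Tensor(np.zeros((1, 4, 4, 5))))


class TestResidualStack:
    def test_single_block_equals_stack_of_one(self):
        stack = ResidualStack(6, 1, HP, _rng()).eval()
        x = Tensor(np.random.default_rng(9).normal(size=(1, 4, 4, 6)))
        assert np.array_equal(stack(x).data, stack.blocks[0](x).data)

    def test_four_zeroed_blocks_compose_to_identity(self):
        stack = ResidualStack(6, 4, HP, _rng()).eval()
        for block in stack.blocks:
            for conv in (block.conv1, block.conv2):
                conv.weight.data[:] = 0.0
                conv.bias.data[:] = 0.0
            for bn in (block.bn1, block.bn2):
                _identity_bn(bn)
        x = np.random.default_rng(10).normal(size=(1, 5, 5, 6))
        assert np.array_equal(stack(Tensor(x)).data, x)

    def test_shape_preserved_for_depth_four(self):
        stack = ResidualStack(320, 4, HP, _rng()).eval()
        x = Tensor(np.random.default_rng(11).normal(size=(1, 15, 10, 320)))
        assert stack(x).shape == (1, 15, 10, 320)


class TestAttentionGate:
    def test_hand_computed_scalar_case(self):
        """x=1, g=0, W_x=2, W_g=3, psi=1, zero biases -> alpha=sigmoid(2)."""
        gate = AttentionGate(1, 1, 1, HP, _rng(), upsample_mode="nearest")
        gate.w_x.weight.data[:] = 2.0
        gate.w_g.weight.data[:] = 3.0
        gate.w_g.bias.data[:] = 0.0
        gate.psi.weight.data[:] = 1.0
        gate.psi.bias.data[:] = 0.0
        x = Tensor(np.ones((1, 2, 2, 1)))
        g = Tensor(np.zeros((1, 1, 1, 1)))
        gated, alpha = gate(x, g)
        expected = 1.0 / (1.0 + np.exp(-2.0))
        assert alpha.data == pytest.approx(expected, abs=1e-5)
        assert float(alpha.data.ravel()[0]) == pytest.approx(0.88080, abs=1e-5)
        assert gated.data == pytest.approx(expected, abs=1e-5)

    def test_zero_psi_yields_half_alpha_and_halved_features(self):
        gate = AttentionGate(3, 5, 2, HP, _rng())
        gate.psi.weight.data[:] = 0.0
        gate.psi.bias.data[:] = 0.0
        x = Tensor(np.random.default_rng(12).normal(size=(1, 8, 8, 3)))
        g = Tensor(np.random.default_rng(13).normal(size=(1, 4, 4, 5)))
        gated, alpha = gate(x, g)
        assert np.all(alpha.data == 0.5)
        assert np.array_equal(gated.data, 0.5 * x.data)

    def test_alpha_strictly_inside_unit_interval(self):
        gate = AttentionGate(3, 5, 2, HP, _rng())
        x = Tensor(np.random.default_rng(14).normal(size=(1, 8, 8, 3)))
        g = Tensor(np.random.default_rng(15).normal(size=(1, 4, 4, 5)))
        _, alpha = gate(x, g)
        assert alpha.shape[-1] == 1
        assert np.all(alpha.data > 0.0) and np.all(alpha.data < 1.0)

    def test_resolution_mismatch_raises(self):
        gate = AttentionGate(3, 5, 2, HP, _rng())
        with pytest.raises(InvalidShapeError):
            gate(Tensor(np.zeros((1, 8, 8, 3))),
                 Tensor(np.zeros((1, 3, 4, 5))))


class TestOutputHead:
    def test_doubles_dims_to_single_channel_in_unit_interval(self):
        head = OutputHead(20, 1, HP, _rng())
        x = Tensor(np.random.default_rng(16).normal(size=(1, 24, 16, 20)))
        out = head(x)
        assert out.shape == (1, 48, 32, 1)
        assert np.all(out.data > 0.0) and np.all(out.data < 1.0)

    def test_zero_weights_give_half_everywhere(self):
        head = OutputHead(4, 1, HP, _rng())
        head.deconv.weight.data[:] = 0.0
        head.deconv.bias.data[:] = 0.0
        out = head(Tensor(np.random.default_rng(17).normal(size=(1, 4, 4, 4))))
        assert np.all(out.data == 0.5)


class TestSingleNet:
    def test_encoder_channel_progression_matches_config(self, reduced_cfg):
        net = build_single_net(reduced_cfg, seed=0).eval()
        h = Tensor(np.random.default_rng(18).normal(size=(1, 64, 64, 1)))
        channels = []
        for block in net.encoders:
            h = block(h)
            channels.append(h.shape[-1])
        assert tuple(channels) == reduced_cfg.encoder_filters

    def test_output_matches_input_spatial_dims(self, reduced_cfg):
        net = build_single_net(reduced_cfg, seed=0).eval()
        out, gated = net(Tensor(np.random.default_rng(19).normal(
            size=(1, 64, 96, 1))))
        assert out.shape == (1, 64, 96, 1)
        assert np.all(out.data > 0.0) and np.all(out.data < 1.0)
        assert len(gated) == len(reduced_cfg.decoder_filters)

    def test_indivisible_input_raises(self, reduced_cfg):
        net = build_single_net(reduced_cfg, seed=0).eval()
        with pytest.raises(InvalidShapeError, match="divisible"):
            net(Tensor(np.zeros((1, 60, 64, 1))))


class TestDoubleNet:
    def test_both_outputs_match_input_shape(self, reduced_cfg):
        model = assemble_double_net(reduced_cfg, seed=0).eval()
        x = Tensor(np.random.default_rng(20).normal(size=(1, 64, 64, 1)))
        out1, out2 = model(x)
        assert out1.shape == out2.shape == (1, 64, 64, 1)
        for out in (out1, out2):
            assert np.all(out.data > 0.0) and np.all(out.data < 1.0)

    def test_net2_decoder_concatenates_both_networks_gates(self, reduced_cfg):
        """NET2 decoder input channels = deconv filters + 2 x gate channels."""
        model = assemble_double_net(reduced_cfg, seed=0)
        enc = reduced_cfg.encoder_filters
        dec = reduced_cfg.decoder_filters
        for i, block in enumerate(model.net2.decoders[1:], start=1):
            scale = len(dec) - i  # encoder scale gated by decoder i-1
            expected_cin = dec[i - 1] + 2 * enc[scale]
            assert block.deconv.weight.data.shape[2] == expected_cin

    def test_parameter_count_invariant_across_seeds(self, reduced_cfg):
        a = assemble_double_net(reduced_cfg, seed=1)
        b = assemble_double_net(reduced_cfg, seed=999)
        assert count_parameters(a) == count_parameters(b)

    def test_seeded_assembly_is_reproducible(self, reduced_cfg):
        a = assemble_double_net(reduced_cfg, seed=42).eval()
        b = assemble_double_net(reduced_cfg, seed=42).eval()
        for (na, pa), (nb, pb) in zip(a.named_parameters(),
                                      b.named_parameters()):
            assert na == nb
            assert np.array_equal(pa.data, pb.data)
        x = Tensor(np.random.default_rng(21).normal(size=(1, 32, 32, 1)))
        oa = a(x)
        ob = b(x)
        assert np.array_equal(oa[1].data, ob[1].data)

    def test_gradient_reaches_every_parameter_group(self, reduced_cfg):
        from darunet.metrics import dice_loss

        model = assemble_double_net(reduced_cfg, seed=3).eval()
        r = np.random.default_rng(22)
        x = Tensor(r.normal(size=(1, 32, 32, 1)))
        target = Tensor((r.random((1, 32, 32, 1)) > 0.7).astype(float))
        out1, out2 = model(x)
        loss = dice_loss(out2, target) + 0.5 * dice_loss(out1, target)
        loss.backward()
        groups = {}
        for name, p in model.named_parameters():
            key = ".".join(name.split(".")[:2])
            nonzero = p.grad is not None and np.any(p.grad != 0)
            groups[key] = groups.get(key, False) or nonzero
        assert groups, "no parameters found"
        missing = [k for k, ok in groups.items() if not ok]
        assert not missing, f"zero gradient in groups: {missing}"


def closed_form_parameter_count(cfg: NetworkConfig, n_skip_sources: int
                                ) -> int:
    """Independent layer-walk count from the architecture definition."""
    k = cfg.hyper.kernel_size
    total = 0
    cin = cfg.output_channels
    for f in cfg.encoder_filters:  # conv + bias + bn
        total += k * k * cin * f + f + 2 * f
        cin = f
    rf = cfg.residual_filters
    total += cfg.n_residual_blocks * 2 * (k * k * rf * rf + rf + 2 * rf)
    n_dec = len(cfg.decoder_filters)
    g_ch = rf
    for i, f in enumerate(cfg.decoder_filters):
        scale = n_dec - 1 - i
        f_l = cfg.encoder_filters[scale]
        f_int = cfg.f_int(scale)
        total += f_l * f_int                  # W_x, 1x1, no bias
        total += g_ch * f_int + f_int         # W_g + b_g
        total += f_int + 1                    # psi + b_psi
        total += k * k * g_ch * f + f + 2 * f  # deconv + bias + bn
        g_ch = f + n_skip_sources * f_l
    total += k * k * g_ch * cfg.output_channels + cfg.output_channels
    return total


def test_parameter_count_matches_closed_form(reduced_cfg):
    model = assemble_double_net(reduced_cfg, seed=0)
    expected = (closed_form_parameter_count(reduced_cfg, 1)
                + closed_form_parameter_count(reduced_cfg, 2))
    assert count_parameters(model) == expected
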