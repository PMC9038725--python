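"""Double Attention Res-U-Net architecture.

Two structurally identical attention-gated residual U-Nets are chained:
NET1 produces a salient probability map from the input image, NET2 sees
the input re-weighted by that map (element-wise product) and produces
the final segmentation. Each network has five stride-2 encoder blocks,
a stack of residual blocks at the bottleneck, four attention-gated
decoder blocks and a transposed-convolution sigmoid output head. NET2's
decoder additionally concatenates NET1's attention-gate outputs at the
matching scale, so gradients flow through both networks.

The attention gate computes, for skip features x and a coarser gating
signal g,

    q     = psi( sigma1( W_x x + W_g up2(g) + b_g ) ) + b_psi
    alpha = sigmoid(q),      gated = x * alpha

with 1x1 convolutions W_x (no bias), W_g (bias b_g) and psi (bias
b_psi), sigma1 a ReLU, and alpha a single channel broadcast over x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .config import LayerHyperParams, NetworkConfig
from .layers import BatchNorm2d, Conv2d, ConvTranspose2d, Module

__all__ = [
    "InvalidShapeError", "EncoderBlock", "DecoderBlock", "ResidualBlock",
    "ResidualStack", "AttentionGate", "OutputHead", "SingleNet", "DoubleNet",
    "PredictionPair", "build_single_net", "assemble_double_net",
    "count_parameters",
]


class InvalidShapeError(ValueError):
    """A feature map has a spatial or channel shape the layer cannot take."""


@dataclass
class PredictionPair:
    """NET1 salient map and NET2 final probability map, as arrays."""

    out1: np.ndarray
    out2: np.ndarray


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class EncoderBlock(Module):
    """conv(5x5, stride 2, same) -> batch-norm -> leaky ReLU(0.2)."""

    def __init__(self, cin: int, filters: int, hp: LayerHyperParams,
                 rng: np.random.Generator):
        super().__init__()
        if filters <= 0:
            raise ValueError("filters must be positive")
        self.hp = hp
        self.conv = Conv2d(cin, filters, hp.kernel_size, stride=hp.stride,
                           init_std=hp.init_std, rng=rng)
        self.bn = BatchNorm2d(filters)

    def __call__(self, x) -> Tensor:
        x = _as_tensor(x)
        if x.ndim != 4 or min(x.shape) < 1:
            raise InvalidShapeError(f"expected NHWC input, got {x.shape}")
        return self.bn(self.conv(x)).leaky_relu(self.hp.leaky_slope)


class DecoderBlock(Module):
    """deconv(5x5, stride 2) -> batch-norm -> dropout -> concat skips -> ReLU."""

    def __init__(self, cin: int, filters: int, hp: LayerHyperParams,
                 rng: np.random.Generator):
        super().__init__()
        self.hp = hp
        self.deconv = ConvTranspose2d(cin, filters, hp.kernel_size,
                                      stride=hp.stride, init_std=hp.init_std,
                                      rng=rng)
        self.bn = BatchNorm2d(filters)

    def __call__(self, x, skips: list, rng: np.random.Generator | None = None
                 ) -> Tensor:
        x = _as_tensor(x)
        up = self.bn(self.deconv(x))
        for s in skips:
            if (s.shape[1], s.shape[2]) != (up.shape[1], up.shape[2]):
                raise InvalidShapeError(
                    f"skip spatial {s.shape[1:3]} != upsampled {up.shape[1:3]}")
        if self.training and self.hp.dropout_rate > 0:
            if rng is None:
                rng = np.random.default_rng()
            up = up.dropout(self.hp.dropout_rate, rng)
        return concat([up] + [_as_tensor(s) for s in skips]).relu()


class ResidualBlock(Module):
    """x + F(x), F = bn2 . conv2 . bn1 . conv1 (5x5, stride 1, same).

    No nonlinearity follows the second convolution, so a zeroed branch
    leaves the block an exact identity mapping.
    """

    def __init__(self, filters: int, hp: LayerHyperParams,
                 rng: np.random.Generator):
        super().__init__()
        self.filters = filters
        self.conv1 = Conv2d(filters, filters, hp.kernel_size,
                            stride=hp.residual_stride, init_std=hp.init_std,
                            rng=rng)
        self.bn1 = BatchNorm2d(filters)
        self.conv2 = Conv2d(filters, filters, hp.kernel_size,
                            stride=hp.residual_stride, init_std=hp.init_std,
                            rng=rng)
        self.bn2 = BatchNorm2d(filters)

    def branch(self, x) -> Tensor:
        return self.bn2(self.conv2(self.bn1(self.conv1(_as_tensor(x)))))

    def __call__(self, x) -> Tensor:
        x = _as_tensor(x)
        if x.shape[-1] != self.filters:
            raise InvalidShapeError(
                f"residual block expects {self.filters} channels, "
                f"got {x.shape[-1]}")
        return self.branch(x) + x


class ResidualStack(Module):
    """`n` residual blocks applied in sequence (shape preserving)."""

    def __init__(self, filters: int, n: int, hp: LayerHyperParams,
                 rng: np.random.Generator):
        super().__init__()
        if n < 1:
            raise ValueError("need at least one residual block")
        self.blocks = [ResidualBlock(filters, hp, rng) for _ in range(n)]

    def __call__(self, x) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return x


class AttentionGate(Module):
    """Additive attention gate producing a single-channel map alpha in (0,1)."""

    def __init__(self, f_l: int, f_g: int, f_int: int,
                 hp: LayerHyperParams, rng: np.random.Generator,
                 upsample_mode: str = "bilinear"):
        super().__init__()
        self.upsample_mode = upsample_mode
        self.w_x = Conv2d(f_l, f_int, kernel_size=1, stride=1,
                          init_std=hp.init_std, bias=False, rng=rng)
        self.w_g = Conv2d(f_g, f_int, kernel_size=1, stride=1,
                          init_std=hp.init_std, rng=rng)  # bias = b_g
        self.psi = Conv2d(f_int, 1, kernel_size=1, stride=1,
                          init_std=hp.init_std, rng=rng)  # bias = b_psi

    def __call__(self, x, g) -> tuple[Tensor, Tensor]:
        """Return (gated, alpha); g must sit one stride-2 level below x."""
        x, g = _as_tensor(x), _as_tensor(g)
        if (g.shape[1] * 2, g.shape[2] * 2) != (x.shape[1], x.shape[2]):
            raise InvalidShapeError(
                f"gating signal {g.shape[1:3]} is not half of x {x.shape[1:3]}")
        g_up = g.upsample2x(self.upsample_mode)
        q = self.psi((self.w_x(x) + self.w_g(g_up)).relu())
        alpha = q.sigmoid()
        return x * alpha, alpha


class OutputHead(Module):
    """Transposed conv 5x5 stride 2 to `cout` channels, sigmoid activation."""

    def __init__(self, cin: int, cout: int, hp: LayerHyperParams,
                 rng: np.random.Generator):
        super().__init__()
        self.deconv = ConvTranspose2d(cin, cout, hp.kernel_size,
                                      stride=hp.stride, init_std=hp.init_std,
                                      rng=rng)

    def __call__(self, x) -> Tensor:
        return self.deconv(_as_tensor(x)).sigmoid()


class SingleNet(Module):
    """One attention-gated residual U-Net.

    `n_skip_sources` is the number of attention-gate outputs each
    decoder block concatenates (1 for NET1; 2 for NET2, which reuses
    NET1's gate outputs at the matching scale).
    """

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator,
                 n_skip_sources: int = 1):
        super().__init__()
        self.cfg = cfg
        self.n_skip_sources = n_skip_sources
        hp = cfg.hyper
        enc = cfg.encoder_filters
        dec = cfg.decoder_filters
        n_dec = len(dec)

        encoders, cin = [], cfg.output_channels
        for f in enc:
            encoders.append(EncoderBlock(cin, f, hp, rng))
            cin = f
        self.encoders = encoders
        self.residuals = ResidualStack(cfg.residual_filters,
                                       cfg.n_residual_blocks, hp, rng)

        # decoder i consumes the feature at scale (n_dec - i) and emits
        # scale (n_dec - i - 1); its attention gate takes x = encoder
        # output at that target scale and g = the consumed feature.
        gates, decoders = [], []
        g_ch = cfg.residual_filters
        for i in range(n_dec):
            scale = n_dec - 1 - i            # encoder scale gated here
            f_l = enc[scale]
            gates.append(AttentionGate(f_l, g_ch, cfg.f_int(scale), hp, rng,
                                       upsample_mode=cfg.upsample_mode))
            decoders.append(DecoderBlock(g_ch, dec[i], hp, rng))
            g_ch = dec[i] + n_skip_sources * f_l
        self.gates = gates
        self.decoders = decoders
        self.head = OutputHead(g_ch, cfg.output_channels, hp, rng)

    def _check_input(self, x: Tensor):
        div = self.cfg.spatial_divisor
        if x.ndim != 4:
            raise InvalidShapeError(f"expected NHWC input, got shape {x.shape}")
        if x.shape[1] % div or x.shape[2] % div:
            raise InvalidShapeError(
                f"input spatial dims {x.shape[1:3]} must be divisible by {div}"
                " (pad first; see darunet.data.pad_to_multiple)")

    def __call__(self, x, cross_skips: list | None = None,
                 dropout_rng: np.random.Generator | None = None
                 ) -> tuple[Tensor, list]:
        """Forward pass.

        Returns (probability map, attention-gate outputs ordered from
        the deepest to the shallowest decoded scale) so a second
        network can concatenate them at matching scales.
        """
        x = _as_tensor(x)
        self._check_input(x)
        feats = []
        h = x
        for block in self.encoders:
            h = block(h)
            feats.append(h)
        h = self.residuals(h)
        n_dec = len(self.decoders)
        if cross_skips is not None and len(cross_skips) != n_dec:
            raise InvalidShapeError(
                f"expected {n_dec} cross-network skips, got {len(cross_skips)}")
        gated_maps = []
        for i, (gate, decoder) in enumerate(zip(self.gates, self.decoders)):
            scale = n_dec - 1 - i
            gated, _alpha = gate(feats[scale], h)
            skips = [gated]
            if cross_skips is not None:
                skips.append(cross_skips[i])
            gated_maps.append(gated)
            h = decoder(h, skips, rng=dropout_rng)
        return self.head(h), gated_maps


class DoubleNet(Module):
    """The two-network composition: out1 = net1(x), out2 = net2(out1 * x)."""

    def __init__(self, cfg: NetworkConfig, seed: int | None = None):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.net1 = SingleNet(cfg, rng, n_skip_sources=1)
        self.net2 = SingleNet(cfg, rng, n_skip_sources=2)

    def __call__(self, x, dropout_rng: np.random.Generator | None = None
                 ) -> tuple[Tensor, Tensor]:
        x = _as_tensor(x)
        out1, skips1 = self.net1(x, dropout_rng=dropout_rng)
        out2, _ = self.net2(out1 * x, cross_skips=skips1,
                            dropout_rng=dropout_rng)
        return out1, out2

    def predict_arrays(self, x: np.ndarray) -> PredictionPair:
        """Inference-mode forward returning plain arrays."""
        was_training = self.training
        self.eval()
        try:
            out1, out2 = self(Tensor(x))
        finally:
            self.train(was_training)
        return PredictionPair(out1=out1.data, out2=out2.data)


def build_single_net(cfg: NetworkConfig, seed: int | None = None,
                     n_skip_sources: int = 1) -> SingleNet:
    """Construct one attention-gated residual U-Net from `cfg`."""
    return SingleNet(cfg, np.random.default_rng(seed),
                     n_skip_sources=n_skip_sources)


def assemble_double_net(cfg: NetworkConfig, seed: int | None = None
                        ) -> DoubleNet:
    """Construct the full two-network model with seeded initialisation."""
    return DoubleNet(cfg, seed=seed)


def count_parameters(model: Module) -> int:
    """Number of trainable scalars (running statistics excluded)."""
    return int(sum(p.data.size for p in model.parameters()))
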