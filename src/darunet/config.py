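"""Configuration dataclasses for the Double Attention Res-U-Net stack."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

__all__ = ["LayerHyperParams", "NetworkConfig", "TrainConfig", "SynthConfig",
           "REDUCED_ENCODER_FILTERS", "REDUCED_DECODER_FILTERS"]

# desk-scale width used for fast experiments and tests
REDUCED_ENCODER_FILTERS = (4, 8, 16, 32, 64)
REDUCED_DECODER_FILTERS = (32, 16, 8, 4)


@dataclass
class LayerHyperParams:
    """Shared layer hyper-parameters.

    kernel_size 5 and stride 2 drive every encoder/decoder convolution;
    residual convolutions run at stride 1. Weights start from a
    zero-mean normal with std `init_std`; encoder activations are leaky
    rectifiers with slope `leaky_slope`; decoder blocks apply dropout
    with probability `dropout_rate` during training.
    """

    kernel_size: int = 5
    stride: int = 2
    residual_stride: int = 1
    init_std: float = 0.02
    leaky_slope: float = 0.2
    dropout_rate: float = 0.3
    padding: str = "same"

    def __post_init__(self):
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.init_std <= 0:
            raise ValueError("init_std must be positive")
        if not 0 <= self.leaky_slope < 1:
            raise ValueError("leaky_slope must be in [0, 1)")
        if self.padding != "same":
            raise ValueError("only 'same' padding is supported")


@dataclass
class NetworkConfig:
    """Architecture description for one (or both) of the twin networks.

    Defaults are the published full-width configuration: five encoder
    blocks (20..320 filters), four residual blocks at the bottleneck,
    four decoder blocks (160..20 filters) and a single-channel sigmoid
    output head. `attention_intermediate` fixes the attention gates'
    intermediate channel count F_int per scale; None means F_l // 2
    (at least 1) at each gate.
    """

    encoder_filters: tuple = (20, 40, 80, 160, 320)
    decoder_filters: tuple = (160, 80, 40, 20)
    n_residual_blocks: int = 4
    residual_filters: int | None = None
    attention_intermediate: tuple | None = None
    output_channels: int = 1
    upsample_mode: str = "bilinear"
    hyper: LayerHyperParams = field(default_factory=LayerHyperParams)

    def __post_init__(self):
        self.encoder_filters = tuple(int(f) for f in self.encoder_filters)
        self.decoder_filters = tuple(int(f) for f in self.decoder_filters)
        if len(self.encoder_filters) != len(self.decoder_filters) + 1:
            raise ValueError(
                "need len(encoder_filters) == len(decoder_filters) + 1")
        if self.n_residual_blocks < 1:
            raise ValueError("n_residual_blocks must be >= 1")
        if any(f <= 0 for f in self.encoder_filters + self.decoder_filters):
            raise ValueError("all filter counts must be positive")
        if self.residual_filters is None:
            self.residual_filters = self.encoder_filters[-1]
        if self.residual_filters != self.encoder_filters[-1]:
            raise ValueError(
                "residual_filters must equal the deepest encoder width")
        if self.upsample_mode not in ("bilinear", "nearest"):
            raise ValueError("upsample_mode must be 'bilinear' or 'nearest'")

    @property
    def n_levels(self) -> int:
        return len(self.encoder_filters)

    @property
    def spatial_divisor(self) -> int:
        """Input spatial dims must be divisible by this (2^levels)."""
        return 2 ** self.n_levels

    def f_int(self, scale: int) -> int:
        """Attention intermediate channels at `scale` (0 = shallowest)."""
        if self.attention_intermediate is not None:
            return int(self.attention_intermediate[scale])
        return max(self.encoder_filters[scale] // 2, 1)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        hyper = d.pop("hyper", {})
        if isinstance(hyper, dict):
            hyper = LayerHyperParams(**hyper)
        ai = d.get("attention_intermediate")
        if ai is not None:
            d["attention_intermediate"] = tuple(ai)
        return cls(hyper=hyper, **d)

    @classmethod
    def reduced(cls, **kwargs) -> "NetworkConfig":
        """Desk-scale configuration for CPU experiments."""
        kwargs.setdefault("encoder_filters", REDUCED_ENCODER_FILTERS)
        kwargs.setdefault("decoder_filters", REDUCED_DECODER_FILTERS)
        return cls(**kwargs)


@dataclass
class TrainConfig:
    """Optimisation settings; defaults follow the published protocol
    (Adam, learning rate 1e-4, batch size 1, minus-Dice objective)."""

    learning_rate: float = 1e-4
    batch_size: int = 1
    epochs: int = 150
    aux_loss_weight: float = 0.5
    seed: int = 0
    deterministic: bool = True
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-7

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.aux_loss_weight < 0:
            raise ValueError("aux_loss_weight must be >= 0")
        if self.batch_size != 1:
            raise ValueError("only batch_size 1 is supported")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


@dataclass
class SynthConfig:
    """Synthetic speckle-phantom generator settings.

    Emulates the character of clinical ultrasound frames: one bright,
    soft-edged connected structure on a textured darker background,
    multiplicative Gamma speckle of unit mean (shape `speckle_shape`),
    a linear top-to-bottom intensity attenuation, and Gaussian blur.
    """

    height: int = 64
    width: int = 64
    n_samples: int = 8
    area_fraction: tuple = (0.08, 0.30)
    fg_mean: float = 0.75
    bg_mean: float = 0.35
    speckle_shape: float = 4.0
    blur_sigma: float = 1.0
    attenuation: float = 0.3
    boundary_roughness: float = 0.15
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.area_fraction
        if not 0 < lo < hi < 1:
            raise ValueError("need 0 < area_fraction min < max < 1")
        if self.fg_mean == self.bg_mean:
            raise ValueError("fg_mean must differ from bg_mean")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if not 0 <= self.attenuation < 1:
            raise ValueError("attenuation must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)
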