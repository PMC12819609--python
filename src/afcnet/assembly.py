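"""Backbone adapter, channel bookkeeping and the full segmentation network.

The encoder contract is a 3-level feature pyramid at strides 4/8/16, each
level reduced to a common channel width by a 1x1 conv + BN + ReLU.  A tiny
random-init backbone ships for CPU tests; the published large backbones
(res2net50 / resnest50 / pvt) would require an external deep-learning
framework and are rejected with a clear configuration error when requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .exceptions import ConfigurationError, NumericError, ShapeError
from .maff import MAFF, AggregatedPyramid
from .mdca import MDCA, DEFAULT_STRIP_KERNELS
from .nd import (
    BatchNorm2d,
    Conv2d,
    ConvBNReLU,
    Module,
    Tensor,
    bilinear_resize,
    count_params,
    seed_all,
)
from .ufr import UFR

KNOWN_BACKBONES = ("tiny_test", "res2net50", "resnest50", "pvt")
UNAVAILABLE_BACKBONES = ("res2net50", "resnest50", "pvt")


@dataclass
class ModelConfig:
    backbone_name: str = "res2net50"
    common_width: int = 64
    input_size: int = 352
    use_mdca: bool = True
    use_maff: bool = True
    use_ufr: bool = True
    pretrained: bool = False
    strip_kernels: tuple[int, ...] = DEFAULT_STRIP_KERNELS
    threshold: float = 0.5

    def __post_init__(self):
        if self.input_size % 16 != 0:
            raise ConfigurationError(f"input_size {self.input_size} not divisible by 16")
        if self.common_width <= 0:
            raise ConfigurationError("common_width must be positive")
        if self.backbone_name not in KNOWN_BACKBONES:
            raise ConfigurationError(
                f"unknown backbone '{self.backbone_name}'; options: {KNOWN_BACKBONES}"
            )
        self.strip_kernels = tuple(self.strip_kernels)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["strip_kernels"] = list(self.strip_kernels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "strip_kernels" in d:
            d["strip_kernels"] = tuple(d["strip_kernels"])
        return cls(**d)


@dataclass
class FeaturePyramid:
    f1: Tensor  # stride 4
    f2: Tensor  # stride 8
    f3: Tensor  # stride 16

    def as_tuple(self):
        return (self.f1, self.f2, self.f3)


@dataclass
class SegmentationOutput:
    probability: Tensor
    binary_mask: np.ndarray
    threshold: float = 0.5


class TinyBackbone(Module):
    """Small strided-conv encoder emitting stride-4/8/16 stages.

    Stage widths w, 2w, 4w with w = common_width//2 (min 8); purely for
    offline CPU testing and the synthetic training protocol.
    """

    def __init__(self, width: int = 16):
        super().__init__()
        w = max(width, 8)
        self.stage_channels = (w, 2 * w, 4 * w)
        self.stem = Conv2d(3, w, 3, stride=2)
        self.stem_bn = BatchNorm2d(w)
        self.layer1 = Conv2d(w, w, 3, stride=2)
        self.bn1 = BatchNorm2d(w)
        self.layer2 = Conv2d(w, 2 * w, 3, stride=2)
        self.bn2 = BatchNorm2d(2 * w)
        self.layer3 = Conv2d(2 * w, 4 * w, 3, stride=2)
        self.bn3 = BatchNorm2d(4 * w)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        s = self.stem_bn(self.stem(x)).relu()
        f1 = self.bn1(self.layer1(s)).relu()
        f2 = self.bn2(self.layer2(f1)).relu()
        f3 = self.bn3(self.layer3(f2)).relu()
        return f1, f2, f3


def _make_backbone(name: str, common_width: int, pretrained: bool) -> TinyBackbone:
    if name in UNAVAILABLE_BACKBONES:
        raise ConfigurationError(
            f"backbone '{name}' requires an external deep-learning framework and "
            "pretrained weights that are not available offline; use 'tiny_test'"
        )
    if pretrained:
        raise ConfigurationError("no pretrained weights exist for the tiny_test backbone")
    return TinyBackbone(width=max(common_width // 2, 8))


class _Reduction(Module):
    def __init__(self, cin: int, cout: int):
        super().__init__()
        self.conv = Conv2d(cin, cout, 1, padding=(0, 0))
        self.bn = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class Encoder(Module):
    """Backbone + per-level 1x1 reduction to the common width."""

    def __init__(self, backbone_name: str, common_width: int, pretrained: bool = False):
        super().__init__()
        self.backbone = _make_backbone(backbone_name, common_width, pretrained)
        c1, c2, c3 = self.backbone.stage_channels
        self.reduce1 = _Reduction(c1, common_width)
        self.reduce2 = _Reduction(c2, common_width)
        self.reduce3 = _Reduction(c3, common_width)

    def forward(self, image: Tensor) -> FeaturePyramid:
        _, c, h, w = image.shape
        if c != 3:
            raise ShapeError(f"expected 3-channel input, got {c}")
        if h % 16 or w % 16:
            raise ShapeError(f"input dims {(h, w)} must be divisible by 16")
        f1, f2, f3 = self.backbone(image)
        return FeaturePyramid(
            f1=self.reduce1(f1), f2=self.reduce2(f2), f3=self.reduce3(f3)
        )


class PlainDecoder(Module):
    """Baseline top-down decoder: 3x3 conv + x2 bilinear per level, 1x1 head."""

    def __init__(self, channels: int):
        super().__init__()
        self.fuse2 = ConvBNReLU(channels, channels)
        self.fuse1 = ConvBNReLU(channels, channels)
        self.out_conv = ConvBNReLU(channels, channels)
        self.head = Conv2d(channels, 1, 1, padding=(0, 0))

    def forward(self, agg: AggregatedPyramid) -> Tensor:
        f1, f2, f3 = agg.as_tuple()
        _, _, h2, w2 = f2.shape
        d = self.fuse2(bilinear_resize(f3, h2, w2) + f2)
        _, _, h1, w1 = f1.shape
        d = self.fuse1(bilinear_resize(d, h1, w1) + f1)
        logits = self.head(self.out_conv(d))
        _, _, h, w = logits.shape
        return bilinear_resize(logits, 4 * h, 4 * w).sigmoid()


class AFCNet(Module):
    """Full pipeline: encoder -> [MDCA x3] -> [MAFF] -> decoder (UFR or plain)."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        c = config.common_width
        self.encoder = Encoder(config.backbone_name, c, config.pretrained)
        if config.use_mdca:
            self.mdca1 = MDCA(c, config.strip_kernels)
            self.mdca2 = MDCA(c, config.strip_kernels)
            self.mdca3 = MDCA(c, config.strip_kernels)
        if config.use_maff:
            self.maff = MAFF(c)
        self.decoder = UFR(c) if config.use_ufr else PlainDecoder(c)

    def extract_pyramid(self, image: Tensor) -> FeaturePyramid:
        return self.encoder(image)

    def forward_probability(self, image: Tensor) -> Tensor:
        pyr = self.encoder(image)
        f1, f2, f3 = pyr.as_tuple()
        if self.config.use_mdca:
            f1 = self.mdca1(f1)
            f2 = self.mdca2(f2)
            f3 = self.mdca3(f3)
        if self.config.use_maff:
            agg = self.maff(f1, f2, f3)
        else:
            agg = AggregatedPyramid(f1, f2, f3)
        prob = self.decoder(agg)
        if not np.all(np.isfinite(prob.data)):
            raise NumericError("non-finite values in network output")
        return prob

    def forward(self, image: Tensor) -> SegmentationOutput:
        prob = self.forward_probability(image)
        mask = (prob.data >= self.config.threshold).astype(np.uint8)
        return SegmentationOutput(
            probability=prob, binary_mask=mask, threshold=self.config.threshold
        )


def build_model(config: ModelConfig, seed: int | None = None) -> AFCNet:
    """Construct an AFCNet; `seed` fixes parameter initialization."""
    if seed is not None:
        seed_all(seed)
    return AFCNet(config)


def parameter_report(model: AFCNet) -> dict:
    """Per-component trainable-parameter subtotals plus the grand total."""
    subtotals: dict[str, int] = {}
    for name, sub in model._modules.items():
        subtotals[name] = count_params(sub)
    return {"total": count_params(model), "by_module": subtotals}
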