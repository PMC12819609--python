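"""Upsampling Feature Retrospective decoder.

GRU-style update/reset gating between adjacent pyramid levels, a concat
fusion per transition, and a projection head restoring input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ConfigurationError, ShapeError
from .nd import BatchNorm2d, Conv2d, ConvBNReLU, Module, Tensor, bilinear_resize, concat
from .maff import AggregatedPyramid


@dataclass
class GateState:
    z_gate: Tensor
    r_gate: Tensor
    candidate: Tensor
    hidden: Tensor
    y_up: Tensor  # the x2-upsampled coarse input, reused by the concat fusion


class GatedUnit(Module):
    """Update/reset gated fusion of a fine feature X with a coarser feature Y.

    Z = sigmoid(relu(BN(conv(X))))          -- update gate
    R = sigmoid(relu(BN(conv(Up2(Y)))))     -- reset gate
    Hbar = tanh(R + relu(BN(conv(R * X))))  -- candidate
    H = Z * X + (1 - Z) * Hbar

    Exactly one x2 bilinear upsampling of Y happens inside the unit.
    `z_override` is a test hook replacing Z with a constant.
    """

    def __init__(self, channels: int):
        super().__init__()
        self.z_conv = Conv2d(channels, channels, 3)
        self.z_bn = BatchNorm2d(channels)
        self.r_conv = Conv2d(channels, channels, 3)
        self.r_bn = BatchNorm2d(channels)
        self.h_conv = Conv2d(channels, channels, 3)
        self.h_bn = BatchNorm2d(channels)

    def forward(self, x: Tensor, y_coarse: Tensor, z_override: float | None = None) -> GateState:
        _, _, hx, wx = x.shape
        _, _, hy, wy = y_coarse.shape
        if (hx, wx) != (2 * hy, 2 * wy):
            raise ShapeError(
                f"coarse input {(hy, wy)} must be exactly half of fine input {(hx, wx)}"
            )
        y_up = bilinear_resize(y_coarse, hx, wx)
        z = self.z_bn(self.z_conv(x)).relu().sigmoid()
        if z_override is not None:
            z = Tensor(z.data * 0 + z_override)
        r = self.r_bn(self.r_conv(y_up)).relu().sigmoid()
        candidate = (r + self.h_bn(self.h_conv(r * x)).relu()).tanh()
        hidden = z * x + (1.0 - z) * candidate
        return GateState(z_gate=z, r_gate=r, candidate=candidate, hidden=hidden, y_up=y_up)


class UFR(Module):
    """Top-down gated decoder over the aggregated pyramid.

    Each level transition gates the finer aggregated map with the coarser
    running feature, concatenates the gate output with the upsampled coarse
    feature and fuses back to the common width; a final conv stage and a
    1x1 head with x4 bilinear upsampling and a logistic map produce the
    full-resolution foreground probability.
    """

    def __init__(self, channels: int):
        super().__init__()
        self.channels = channels
        self.gate32 = GatedUnit(channels)  # level 3 -> level 2
        self.fuse2 = ConvBNReLU(2 * channels, channels)
        self.gate21 = GatedUnit(channels)  # level 2 -> level 1
        self.fuse1 = ConvBNReLU(2 * channels, channels)
        self.out_conv = ConvBNReLU(channels, channels)
        self.head = Conv2d(channels, 1, 1, padding=(0, 0))

    def forward(self, agg: AggregatedPyramid) -> Tensor:
        f1, f2, f3 = agg.as_tuple()
        for name, t in (("f1", f1), ("f2", f2), ("f3", f3)):
            if t is None:
                raise ConfigurationError(f"missing pyramid level {name}")
        gs2 = self.gate32(f2, f3)
        f2_up = self.fuse2(concat([gs2.hidden, gs2.y_up], axis=1))
        gs1 = self.gate21(f1, f2_up)
        f1_up = self.fuse1(concat([gs1.hidden, gs1.y_up], axis=1))
        out = self.out_conv(f1_up)
        logits = self.head(out)
        _, _, h, w = logits.shape
        logits = bilinear_resize(logits, 4 * h, 4 * w)
        return logits.sigmoid()
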