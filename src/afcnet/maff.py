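"""Multi-scale Adaptive Feature Fusion.

Cross-scale alignment by bilinear resampling plus conv/BN/ReLU refinement,
then a cascade of six learnable addition/subtraction mixers (AMFH) producing
one aggregated map per pyramid level.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .exceptions import ConfigurationError, ShapeError
from .nd import BatchNorm2d, Conv2d, Module, Parameter, Tensor, bilinear_resize

import numpy as np


class Align(Module):
    """Bilinear rescale by a fixed factor followed by 3x3 conv + BN + ReLU."""

    _FACTORS = (Fraction(1, 4), Fraction(1, 2), Fraction(2), Fraction(4))

    def __init__(self, channels: int, factor: Fraction | float):
        super().__init__()
        factor = Fraction(factor).limit_denominator(16)
        if factor not in self._FACTORS:
            raise ConfigurationError(f"unsupported alignment factor {factor}")
        self.factor = factor
        self.conv = Conv2d(channels, channels, 3)
        self.bn = BatchNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        th = h * self.factor
        tw = w * self.factor
        if th.denominator != 1 or tw.denominator != 1:
            raise ShapeError(
                f"spatial dims {(h, w)} not divisible for factor {self.factor}"
            )
        y = bilinear_resize(x, int(th), int(tw))
        return self.bn(self.conv(y)).relu()


class AMFH(Module):
    """Learnable mix of feature addition and absolute feature difference.

    The mixing ratio is an unconstrained scalar squashed through a logistic
    to (0, 1); at init the effective ratio is ~0.525 rather than exactly 0.5:
    at w = 0.5 the mix w(x+y) + (1-w)(x-y) has d/dy = 2w-1 = 0, which would
    cut all gradient flow into the second operand until w itself moves.
    """

    def __init__(self, channels: int):
        super().__init__()
        self.raw_weight = Parameter(np.full(1, 0.1))
        self.conv = Conv2d(channels, channels, 3)
        self.bn = BatchNorm2d(channels)

    @property
    def mixing_ratio(self) -> float:
        return float(1.0 / (1.0 + np.exp(-self.raw_weight.data[0])))

    def mixed(self, x: Tensor, y: Tensor) -> Tensor:
        """The pre-conv |w(x+y) + (1-w)(x-y)| term."""
        if x.shape != y.shape:
            raise ShapeError(f"AMFH operands differ in shape: {x.shape} vs {y.shape}")
        w = self.raw_weight.sigmoid().reshape(1, 1, 1, 1)
        return (w * (x + y) + (1.0 - w) * (x - y)).abs()

    def forward(self, x: Tensor, y: Tensor) -> Tensor:
        return self.bn(self.conv(self.mixed(x, y))).relu()


@dataclass
class AggregatedPyramid:
    f1_agg: Tensor
    f2_agg: Tensor
    f3_agg: Tensor

    def as_tuple(self):
        return (self.f1_agg, self.f2_agg, self.f3_agg)


class MAFF(Module):
    """Cross-scale alignment + cascaded AMFH fusion over a 3-level pyramid.

    AMFH mixing ratios are consumed inner-then-outer, level 1 to 3:
    W1,W2 build f1_agg, W3,W4 build f2_agg, W5,W6 build f3_agg.
    """

    def __init__(self, channels: int):
        super().__init__()
        self.channels = channels
        self.align_f1_down2 = Align(channels, Fraction(1, 2))
        self.align_f1_down4 = Align(channels, Fraction(1, 4))
        self.align_f2_up2 = Align(channels, Fraction(2))
        self.align_f2_down2 = Align(channels, Fraction(1, 2))
        self.align_f3_up2 = Align(channels, Fraction(2))
        self.align_f3_up4 = Align(channels, Fraction(4))
        self.amfh1 = AMFH(channels)  # W1: inner, level 1
        self.amfh2 = AMFH(channels)  # W2: outer, level 1
        self.amfh3 = AMFH(channels)  # W3: inner, level 2
        self.amfh4 = AMFH(channels)  # W4: outer, level 2
        self.amfh5 = AMFH(channels)  # W5: inner, level 3
        self.amfh6 = AMFH(channels)  # W6: outer, level 3

    def mixing_ratios(self) -> list[float]:
        return [getattr(self, f"amfh{i}").mixing_ratio for i in range(1, 7)]

    def forward(self, f1: Tensor, f2: Tensor, f3: Tensor) -> AggregatedPyramid:
        for name, t in (("f1", f1), ("f2", f2), ("f3", f3)):
            if t.shape[1] != self.channels:
                raise ConfigurationError(
                    f"{name} has {t.shape[1]} channels; MAFF expects {self.channels}"
                )
        f1_d2 = self.align_f1_down2(f1)
        f1_d4 = self.align_f1_down4(f1)
        f2_u2 = self.align_f2_up2(f2)
        f2_d2 = self.align_f2_down2(f2)
        f3_u2 = self.align_f3_up2(f3)
        f3_u4 = self.align_f3_up4(f3)
        f1_agg = self.amfh2(self.amfh1(f1, f2_u2), f3_u4)
        f2_agg = self.amfh4(self.amfh3(f1_d2, f2), f3_u2)
        f3_agg = self.amfh6(self.amfh5(f1_d4, f2_d2), f3)
        return AggregatedPyramid(f1_agg, f2_agg, f3_agg)
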