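"""Multi-scale Depth-wise Convolution Attention block.

A 5x5 depthwise-separable pre-convolution feeds three parallel strip-kernel
branches (1xk then kx1 depthwise-separable pairs, k in {7, 11, 21}).  The
branch outputs plus the pre-feature form a multiplicative attention map over
the block input; the gated feature is concatenated with the input and fused
back to the original width by a depthwise-separable 3x3 with BN and ReLU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, NumericError, ShapeError
from .nd import BatchNorm2d, Conv2d, Module, Tensor, concat

DEFAULT_STRIP_KERNELS = (7, 11, 21)


class DepthwiseSeparableConv(Module):
    """Per-channel m x n convolution followed by a 1x1 point-wise channel mixer."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int | tuple[int, int],
    ):
        super().__init__()
        if isinstance(kernel_size, int):
            kernel_size = (kernel_size, kernel_size)
        kh, kw = kernel_size
        if kh % 2 == 0 or kw % 2 == 0:
            raise ConfigurationError(
                f"depthwise kernel dims must be odd to preserve spatial size, got {kernel_size}"
            )
        self.depthwise = Conv2d(
            in_channels, in_channels, (kh, kw), padding=(kh // 2, kw // 2), groups=in_channels
        )
        self.pointwise = Conv2d(in_channels, out_channels, 1, padding=(0, 0))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.depthwise.in_channels:
            raise ShapeError(
                f"expected {self.depthwise.in_channels} channels, got {x.shape[1]}"
            )
        return self.pointwise(self.depthwise(x))


def dws_conv(x: Tensor, block: DepthwiseSeparableConv) -> Tensor:
    """Functional alias: apply a depthwise-separable convolution block."""
    return block(x)


class StripBranch(Module):
    """1xk depthwise-separable conv followed by kx1; approximates a kxk field."""

    def __init__(self, channels: int, k: int, strict: bool = True):
        super().__init__()
        if strict and k not in DEFAULT_STRIP_KERNELS:
            raise ConfigurationError(f"strip kernel {k} not in {DEFAULT_STRIP_KERNELS}")
        if k % 2 == 0:
            raise ConfigurationError(f"strip kernel must be odd, got {k}")
        self.k = k
        self.horizontal = DepthwiseSeparableConv(channels, channels, (1, k))
        self.vertical = DepthwiseSeparableConv(channels, channels, (k, 1))

    def forward(self, x: Tensor) -> Tensor:
        return self.vertical(self.horizontal(x))


@dataclass
class MDCAState:
    """All intermediates of one attention pass, exposed for testing."""

    input: Tensor
    pre: Tensor
    branches: dict[int, Tensor]
    gated: Tensor
    output: Tensor


class MDCA(Module):
    """The full attention block; `forward` returns the output feature map and
    `forward_state` additionally exposes every intermediate."""

    def __init__(self, channels: int, strip_kernels: tuple[int, ...] = DEFAULT_STRIP_KERNELS):
        super().__init__()
        self.channels = channels
        self.strip_kernels = tuple(strip_kernels)
        self.pre_conv = DepthwiseSeparableConv(channels, channels, 5)
        for k in self.strip_kernels:
            setattr(self, f"branch{k}", StripBranch(channels, k, strict=False))
        self.fuse = DepthwiseSeparableConv(2 * channels, channels, 3)
        self.fuse_bn = BatchNorm2d(channels)

    def forward_state(self, x: Tensor) -> MDCAState:
        if x.shape[1] != self.channels:
            raise ShapeError(f"MDCA configured for {self.channels} channels, got {x.shape[1]}")
        pre = self.pre_conv(x)
        branches = {k: getattr(self, f"branch{k}")(pre) for k in self.strip_kernels}
        attention = pre
        for k in self.strip_kernels:
            attention = attention + branches[k]
        gated = x * attention
        fused = self.fuse_bn(self.fuse(concat([gated, x], axis=1))).relu()
        for name, t in (("pre", pre), ("gated", gated), ("output", fused)):
            if not np.all(np.isfinite(t.data)):
                raise NumericError(f"non-finite values in MDCA stage '{name}'")
        return MDCAState(input=x, pre=pre, branches=branches, gated=gated, output=fused)

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_state(x).output
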