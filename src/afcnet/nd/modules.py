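"""Module/parameter containers in the style of the mainstream DL frameworks."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .functional import conv2d
from .tensor import DTYPE, Tensor

_GLOBAL_RNG = np.random.default_rng(0)


def seed_all(seed: int) -> None:
    """Reset the parameter-initialization RNG (call before building a model)."""
    global _GLOBAL_RNG
    _GLOBAL_RNG = np.random.default_rng(seed)


def _rng() -> np.random.Generator:
    return _GLOBAL_RNG


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_parameters", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._parameters[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # ------------------------------------------------------------- traversal
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._parameters.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, self._buffers[name]
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # ----------------------------------------------------------- state dicts
    def state_dict(self) -> dict[str, np.ndarray]:
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            d["buffer." + name] = np.asarray(b).copy()
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.asarray(d[name], dtype=DTYPE).copy()
        # buffers need to be pushed back into their owning submodule
        self._load_buffers(d, "")

    def _load_buffers(self, d: dict[str, np.ndarray], prefix: str):
        for name in list(self._buffers):
            key = "buffer." + prefix + name
            if key in d:
                self._set_buffer(name, np.asarray(d[key], dtype=DTYPE).copy())
        for name, m in self._modules.items():
            m._load_buffers(d, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Grouped 2-D convolution with zero padding preserving spatial size by default."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int | tuple[int, int],
        stride: int = 1,
        padding: tuple[int, int] | str = "same",
        groups: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        if isinstance(kernel_size, int):
            kernel_size = (kernel_size, kernel_size)
        kh, kw = kernel_size
        if padding == "same":
            if kh % 2 == 0 or kw % 2 == 0:
                raise ValueError("'same' padding requires odd kernel dims")
            padding = (kh // 2, kw // 2)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = (kh, kw)
        self.stride = stride
        self.padding = padding
        self.groups = groups
        fan_in = (in_channels // groups) * kh * kw
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            _rng().normal(0.0, std, size=(out_channels, in_channels // groups, kh, kw))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(
            x, self.weight, self.bias, stride=self.stride, padding=self.padding, groups=self.groups
        )


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))

    def forward(self, x: Tensor) -> Tensor:
        shape = (1, self.num_features, 1, 1)
        if self.training:
            m = x.mean(axis=(0, 2, 3), keepdims=True)
            v = ((x - m) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = v.data.reshape(-1) * (n / max(n - 1, 1))
            self._set_buffer(
                "running_mean",
                (1 - self.momentum) * self.running_mean + self.momentum * m.data.reshape(-1),
            )
            self._set_buffer(
                "running_var",
                (1 - self.momentum) * self.running_var + self.momentum * unbiased,
            )
        else:
            m = Tensor(self.running_mean.reshape(shape))
            v = Tensor(self.running_var.reshape(shape))
        xhat = (x - m) / ((v + self.eps) ** 0.5)
        g = self.gamma.reshape(shape)
        b = self.beta.reshape(shape)
        return xhat * g + b


class ConvBNReLU(Module):
    """The 3x3 conv -> BN -> ReLU triple used throughout the network."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, kernel_size)
        self.bn = BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer
            object.__setattr__(self, str(i), layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def count_params(module: Module) -> int:
    """Total number of trainable scalar parameters."""
    return int(sum(p.data.size for p in module.parameters()))
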