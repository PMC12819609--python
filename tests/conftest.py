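import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def identity_conv(conv):
    """Make a square conv the identity map: center-tap-1 kernels, zero bias."""
    conv.weight.data[:] = 0.0
    kh, kw = conv.kernel_size
    for c in range(min(conv.in_channels, conv.out_channels)):
        conv.weight.data[c, c, kh // 2, kw // 2] = 1.0
    if conv.bias is not None:
        conv.bias.data[:] = 0.0


def identity_bn(bn):
    """Make a BatchNorm the identity map (requires eval mode)."""
    bn.eps = 0.0
    bn.gamma.data[:] = 1.0
    bn.beta.data[:] = 0.0
    bn._set_buffer("running_mean", np.zeros(bn.num_features))
    bn._set_buffer("running_var", np.ones(bn.num_features))
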