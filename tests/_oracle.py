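"""Independent reference implementations used as test oracles.

Everything here operates on plain numpy arrays pulled out of the package's
modules (`.data` attributes) and is deliberately written against different
primitives (explicit loops, scipy.ndimage) than the implementation under
test, which uses tap-wise BLAS contractions.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def conv2d_brute(x, w, b=None, padding=(0, 0), groups=1):
    """O(N*Cout*H*W*kh*kw) sliding-window cross-correlation, pure loops."""
    N, C, H, W = x.shape
    Cout, Cin_g, kh, kw = w.shape
    ph, pw = padding
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    Ho = xp.shape[2] - kh + 1
    Wo = xp.shape[3] - kw + 1
    out = np.zeros((N, Cout, Ho, Wo))
    cin_per_group = C // groups
    out_per_group = Cout // groups
    for n in range(N):
        for o in range(Cout):
            g = o // out_per_group
            for hh in range(Ho):
                for ww_ in range(Wo):
                    acc = 0.0
                    for ci in range(cin_per_group):
                        c = g * cin_per_group + ci
                        for i in range(kh):
                            for j in range(kw):
                                acc += xp[n, c, hh + i, ww_ + j] * w[o, ci, i, j]
                    out[n, o, hh, ww_] = acc
            if b is not None:
                out[n, o] += b[o]
    return out


def conv2d_ref(x, w, b=None, groups=1):
    """Same-padding cross-correlation via scipy.ndimage (odd kernels only)."""
    N, C, H, W = x.shape
    Cout, Cin_g, kh, kw = w.shape
    out = np.zeros((N, Cout, H, W))
    cin_per_group = C // groups
    out_per_group = Cout // groups
    for n in range(N):
        for o in range(Cout):
            g = o // out_per_group
            acc = np.zeros((H, W))
            for ci in range(Cin_g):
                c = g * cin_per_group + ci
                acc += ndimage.correlate(x[n, c], w[o, ci], mode="constant", cval=0.0)
            out[n, o] = acc + (b[o] if b is not None else 0.0)
    return out


def dws_ref(x, block):
    """Reference for a depthwise-separable block: depthwise then pointwise."""
    dw = block.depthwise
    pw = block.pointwise
    mid = conv2d_ref(x, dw.weight.data, dw.bias.data, groups=x.shape[1])
    return conv2d_ref(mid, pw.weight.data, pw.bias.data)


def bn_ref(x, bn, training):
    """BatchNorm with biased batch statistics (train) or running stats (eval)."""
    if training:
        m = x.mean(axis=(0, 2, 3), keepdims=True)
        v = x.var(axis=(0, 2, 3), keepdims=True)  # biased, matching normalization
    else:
        m = bn.running_mean.reshape(1, -1, 1, 1)
        v = bn.running_var.reshape(1, -1, 1, 1)
    xhat = (x - m) / np.sqrt(v + bn.eps)
    return xhat * bn.gamma.data.reshape(1, -1, 1, 1) + bn.beta.data.reshape(1, -1, 1, 1)


def conv_bn_relu_ref(x, conv, bn, training):
    y = conv2d_ref(x, conv.weight.data, conv.bias.data)
    return np.maximum(bn_ref(y, bn, training), 0.0)


def bilinear_ref(x, out_h, out_w):
    """Per-pixel bilinear gather, half-pixel centers, edges clamped."""
    N, C, H, W = x.shape
    out = np.zeros((N, C, out_h, out_w))
    for oi in range(out_h):
        cy = min(max((oi + 0.5) * H / out_h - 0.5, 0.0), H - 1.0)
        y0 = int(np.floor(cy))
        y1 = min(y0 + 1, H - 1)
        ty = cy - y0
        for oj in range(out_w):
            cx = min(max((oj + 0.5) * W / out_w - 0.5, 0.0), W - 1.0)
            x0 = int(np.floor(cx))
            x1 = min(x0 + 1, W - 1)
            tx = cx - x0
            out[:, :, oi, oj] = (
                (1 - ty) * (1 - tx) * x[:, :, y0, x0]
                + (1 - ty) * tx * x[:, :, y0, x1]
                + ty * (1 - tx) * x[:, :, y1, x0]
                + ty * tx * x[:, :, y1, x1]
            )
    return out


def sigmoid(a):
    return 1.0 / (1.0 + np.exp(-a))


def mdca_ref(block, x, training):
    """Step-by-step recomputation of the attention block."""
    pre = dws_ref(x, block.pre_conv)
    attention = pre.copy()
    branches = {}
    for k in block.strip_kernels:
        br = getattr(block, f"branch{k}")
        mid = dws_ref(pre, br.horizontal)
        branches[k] = dws_ref(mid, br.vertical)
        attention += branches[k]
    gated = x * attention
    cat = np.concatenate([gated, x], axis=1)
    fused = dws_ref(cat, block.fuse)
    return np.maximum(bn_ref(fused, block.fuse_bn, training), 0.0)


def align_ref(mod, x, training):
    from fractions import Fraction

    f = Fraction(mod.factor)
    th = int(x.shape[2] * f)
    tw = int(x.shape[3] * f)
    y = bilinear_ref(x, th, tw)
    return conv_bn_relu_ref(y, mod.conv, mod.bn, training)


def amfh_ref(mod, x, y, training):
    w = sigmoid(mod.raw_weight.data[0])
    mixed = np.abs(w * (x + y) + (1 - w) * (x - y))
    return conv_bn_relu_ref(mixed, mod.conv, mod.bn, training)


def maff_ref(maff, f1, f2, f3, training):
    f1_d2 = align_ref(maff.align_f1_down2, f1, training)
    f1_d4 = align_ref(maff.align_f1_down4, f1, training)
    f2_u2 = align_ref(maff.align_f2_up2, f2, training)
    f2_d2 = align_ref(maff.align_f2_down2, f2, training)
    f3_u2 = align_ref(maff.align_f3_up2, f3, training)
    f3_u4 = align_ref(maff.align_f3_up4, f3, training)
    a1 = amfh_ref(maff.amfh2, amfh_ref(maff.amfh1, f1, f2_u2, training), f3_u4, training)
    a2 = amfh_ref(maff.amfh4, amfh_ref(maff.amfh3, f1_d2, f2, training), f3_u2, training)
    a3 = amfh_ref(maff.amfh6, amfh_ref(maff.amfh5, f1_d4, f2_d2, training), f3, training)
    return a1, a2, a3


def gated_unit_ref(unit, x, y_coarse, training):
    y_up = bilinear_ref(y_coarse, x.shape[2], x.shape[3])
    z = sigmoid(conv_bn_relu_ref(x, unit.z_conv, unit.z_bn, training))
    r = sigmoid(conv_bn_relu_ref(y_up, unit.r_conv, unit.r_bn, training))
    cand = np.tanh(r + conv_bn_relu_ref(r * x, unit.h_conv, unit.h_bn, training))
    h = z * x + (1 - z) * cand
    return z, r, cand, h, y_up


def ufr_ref(ufr, f1, f2, f3, training):
    _, _, _, h2, y3_up = gated_unit_ref(ufr.gate32, f2, f3, training)
    f2_up = conv_bn_relu_ref(
        np.concatenate([h2, y3_up], axis=1), ufr.fuse2.conv, ufr.fuse2.bn, training
    )
    _, _, _, h1, y2_up = gated_unit_ref(ufr.gate21, f1, f2_up, training)
    f1_up = conv_bn_relu_ref(
        np.concatenate([h1, y2_up], axis=1), ufr.fuse1.conv, ufr.fuse1.bn, training
    )
    out = conv_bn_relu_ref(f1_up, ufr.out_conv.conv, ufr.out_conv.bn, training)
    logits = conv2d_ref(out, ufr.head.weight.data, ufr.head.bias.data)
    logits = bilinear_ref(logits, 4 * logits.shape[2], 4 * logits.shape[3])
    return sigmoid(logits)


def welch_ref(a, b):
    """Textbook Welch statistic + Welch-Satterthwaite df + survival function."""
    from scipy import stats

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va = a.var(ddof=1) / len(a)
    vb = b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return 2 * stats.t.sf(abs(t), df)
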