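"""Spatial primitives: 2-D convolution (grouped) and bilinear resampling."""

from __future__ import annotations

import numpy as np

from .tensor import DTYPE, Tensor


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: tuple[int, int] = (0, 0),
    groups: int = 1,
) -> Tensor:
    """Cross-correlation of NCHW input with (Cout, Cin/groups, kh, kw) weight.

    Zero padding; stride applies to both spatial axes.  Implemented as a sum
    over kernel taps of BLAS-backed channel contractions (shift-and-matmul),
    with a broadcast fast path for depthwise kernels.
    """
    N, C, H, W = x.shape
    Cout, Cin_g, kh, kw = weight.shape
    if C % groups or Cout % groups:
        raise ValueError("channels not divisible by groups")
    if Cin_g != C // groups:
        raise ValueError(
            f"weight expects {Cin_g} in-channels per group, input has {C // groups}"
        )
    ph, pw = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    if Ho <= 0 or Wo <= 0:
        raise ValueError("kernel larger than padded input")

    depthwise = groups == C and Cout == C
    w = weight.data
    out = np.zeros((N, Cout, Ho, Wo), dtype=DTYPE)
    taps = [
        (i, j, xp[:, :, i : i + Ho * stride : stride, j : j + Wo * stride : stride])
        for i in range(kh)
        for j in range(kw)
    ]
    for i, j, sl in taps:
        if depthwise:
            out += sl * w[:, 0, i, j].reshape(1, C, 1, 1)
        elif groups == 1:
            # (Cout, C) . (N, C, Ho, Wo) over C -> (Cout, N, Ho, Wo)
            out += np.tensordot(w[:, :, i, j], sl, axes=([1], [1])).transpose(1, 0, 2, 3)
        else:
            og = Cout // groups
            for g_i in range(groups):
                cs = slice(g_i * Cin_g, (g_i + 1) * Cin_g)
                os_ = slice(g_i * og, (g_i + 1) * og)
                out[:, os_] += np.tensordot(
                    w[os_, :, i, j], sl[:, cs], axes=([1], [1])
                ).transpose(1, 0, 2, 3)
    if bias is not None:
        out += bias.data.reshape(1, Cout, 1, 1)

    prev = (x, weight) + ((bias,) if bias is not None else ())
    req = any(t.requires_grad for t in prev)
    res = Tensor(out, req, prev)

    def _bw(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        gw = np.zeros_like(w) if weight.requires_grad else None
        gxp = np.zeros((N, C, Hp, Wp), dtype=DTYPE) if x.requires_grad else None
        for i, j, sl in taps:
            if gw is not None:
                if depthwise:
                    gw[:, 0, i, j] = (g * sl).sum(axis=(0, 2, 3))
                elif groups == 1:
                    gw[:, :, i, j] = np.tensordot(g, sl, axes=([0, 2, 3], [0, 2, 3]))
                else:
                    og = Cout // groups
                    for g_i in range(groups):
                        cs = slice(g_i * Cin_g, (g_i + 1) * Cin_g)
                        os_ = slice(g_i * og, (g_i + 1) * og)
                        gw[os_, :, i, j] = np.tensordot(
                            g[:, os_], sl[:, cs], axes=([0, 2, 3], [0, 2, 3])
                        )
            if gxp is not None:
                dst = gxp[:, :, i : i + Ho * stride : stride, j : j + Wo * stride : stride]
                if depthwise:
                    dst += g * w[:, 0, i, j].reshape(1, C, 1, 1)
                elif groups == 1:
                    dst += np.tensordot(w[:, :, i, j], g, axes=([0], [1])).transpose(1, 0, 2, 3)
                else:
                    og = Cout // groups
                    for g_i in range(groups):
                        cs = slice(g_i * Cin_g, (g_i + 1) * Cin_g)
                        os_ = slice(g_i * og, (g_i + 1) * og)
                        dst[:, cs] += np.tensordot(
                            w[os_, :, i, j], g[:, os_], axes=([0], [1])
                        ).transpose(1, 0, 2, 3)
        if gw is not None:
            weight._accumulate(gw)
        if gxp is not None:
            x._accumulate(gxp[:, :, ph : Hp - ph or None, pw : Wp - pw or None])

    res._backward = _bw
    return res


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear resampling matrix, half-pixel centers."""
    M = np.zeros((n_out, n_in), dtype=DTYPE)
    scale = n_in / n_out
    for o in range(n_out):
        c = (o + 0.5) * scale - 0.5
        c = min(max(c, 0.0), n_in - 1.0)
        lo = int(np.floor(c))
        hi = min(lo + 1, n_in - 1)
        t = c - lo
        M[o, lo] += 1.0 - t
        M[o, hi] += t
    return M


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Separable bilinear resize of an NCHW tensor (no corner alignment)."""
    N, C, H, W = x.shape
    if out_h <= 0 or out_w <= 0:
        raise ValueError("target size must be positive")
    A = _interp_matrix(H, out_h)
    B = _interp_matrix(W, out_w)
    y = np.einsum("oh,nchw,pw->ncop", A, x.data, B, optimize=True)
    out = Tensor(y, x.requires_grad, (x,))

    def _bw(g):
        if x.requires_grad:
            x._accumulate(np.einsum("oh,ncop,pw->nchw", A, g, B, optimize=True))

    out._backward = _bw
    return out


def bilinear_resize_array(a: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Plain-ndarray bilinear resize (HW or HWC), same convention as above."""
    hwc = a.ndim == 3
    arr = a if hwc else a[:, :, None]
    A = _interp_matrix(arr.shape[0], out_h)
    B = _interp_matrix(arr.shape[1], out_w)
    y = np.einsum("oh,hwc,pw->opc", A, arr.astype(DTYPE), B, optimize=True)
    return y if hwc else y[:, :, 0]
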