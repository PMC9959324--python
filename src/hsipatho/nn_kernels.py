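"""Numba-compiled inner loops for convolution and max-pooling.

Activations flow through the network channels-first — ``(N, C, H, W, B)``
for the 3D variant and ``(N, C, H, W)`` for the 2D variant — so the last
axis (spectral bands, or image columns in 2D) is unit-stride and the hot
loops vectorize.  Weights are ``(C, *kernel, F)``.

Every kernel is a pure function of its arguments; the numpy fallback in
:mod:`hsipatho.nn` computes identical results, and both are checked against
the explicit-sum convolution oracle.  Kernels compile without fastmath so
results are bit-identical across hosts with different SIMD widths.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap


@njit(cache=True)
def conv3d_forward(xp, w, b):
    n_, c_, hp, wp, bp = xp.shape
    _, p_, q_, r_, f_ = w.shape
    h, wd, bands = hp - p_ + 1, wp - q_ + 1, bp - r_ + 1
    out = np.empty((n_, f_, h, wd, bands), dtype=xp.dtype)
    acc = np.empty((f_, bands), dtype=xp.dtype)
    for n in range(n_):
        for i in range(h):
            for j in range(wd):
                for f in range(f_):
                    for k in range(bands):
                        acc[f, k] = b[f]
                for c in range(c_):
                    for p in range(p_):
                        for q in range(q_):
                            row = xp[n, c, i + p, j + q]
                            for f in range(f_):
                                for r in range(r_):
                                    wv = w[c, p, q, r, f]
                                    for k in range(bands):
                                        acc[f, k] += wv * row[k + r]
                for f in range(f_):
                    for k in range(bands):
                        out[n, f, i, j, k] = acc[f, k]
    return out


@njit(cache=True)
def conv3d_backward(xp, w, dy, need_dx):
    n_, c_, hp, wp, bp = xp.shape
    _, p_, q_, r_, f_ = w.shape
    h, wd, bands = hp - p_ + 1, wp - q_ + 1, bp - r_ + 1
    dw = np.zeros(w.shape, dtype=dy.dtype)
    dxp = np.zeros(xp.shape, dtype=dy.dtype)
    for n in range(n_):
        for i in range(h):
            for j in range(wd):
                g = dy[n, :, i, j]
                for c in range(c_):
                    for p in range(p_):
                        for q in range(q_):
                            row = xp[n, c, i + p, j + q]
                            drow = dxp[n, c, i + p, j + q]
                            for r in range(r_):
                                for f in range(f_):
                                    wv = w[c, p, q, r, f]
                                    s = 0.0
                                    for k in range(bands):
                                        s += row[k + r] * g[f, k]
                                    dw[c, p, q, r, f] += s
                                    if need_dx:
                                        for k in range(bands):
                                            drow[k + r] += wv * g[f, k]
    return dw, dxp


@njit(cache=True)
def conv2d_forward(xp, w, b):
    n_, c_, hp, wp = xp.shape
    _, p_, q_, f_ = w.shape
    h, wd = hp - p_ + 1, wp - q_ + 1
    out = np.empty((n_, f_, h, wd), dtype=xp.dtype)
    acc = np.empty((f_, wd), dtype=xp.dtype)
    for n in range(n_):
        for i in range(h):
            for f in range(f_):
                for j in range(wd):
                    acc[f, j] = b[f]
            for c in range(c_):
                for p in range(p_):
                    row = xp[n, c, i + p]
                    for f in range(f_):
                        for q in range(q_):
                            wv = w[c, p, q, f]
                            for j in range(wd):
                                acc[f, j] += wv * row[j + q]
            for f in range(f_):
                for j in range(wd):
                    out[n, f, i, j] = acc[f, j]
    return out


@njit(cache=True)
def conv2d_backward(xp, w, dy, need_dx):
    n_, c_, hp, wp = xp.shape
    _, p_, q_, f_ = w.shape
    h, wd = hp - p_ + 1, wp - q_ + 1
    dw = np.zeros(w.shape, dtype=dy.dtype)
    dxp = np.zeros(xp.shape, dtype=dy.dtype)
    for n in range(n_):
        for i in range(h):
            g = dy[n, :, i]
            for c in range(c_):
                for p in range(p_):
                    row = xp[n, c, i + p]
                    drow = dxp[n, c, i + p]
                    for q in range(q_):
                        for f in range(f_):
                            wv = w[c, p, q, f]
                            s = 0.0
                            for j in range(wd):
                                s += row[j + q] * g[f, j]
                            dw[c, p, q, f] += s
                            if need_dx:
                                for j in range(wd):
                                    drow[j + q] += wv * g[f, j]
    return dw, dxp


@njit(cache=True)
def maxpool3d_forward(x, pool, stride, pad_before, outs):
    n_, c_, h, w, bands = x.shape
    oh, ow, ob = outs
    out = np.empty((n_, c_, oh, ow, ob), dtype=x.dtype)
    arg = np.zeros((n_, c_, oh, ow, ob), dtype=np.int16)
    for n in range(n_):
        for ch in range(c_):
            for oi in range(oh):
                i0 = oi * stride[0] - pad_before[0]
                for oj in range(ow):
                    j0 = oj * stride[1] - pad_before[1]
                    for ok in range(ob):
                        k0 = ok * stride[2] - pad_before[2]
                        best = -np.inf
                        barg = 0
                        off = 0
                        for p in range(pool[0]):
                            i = i0 + p
                            for q in range(pool[1]):
                                j = j0 + q
                                for r in range(pool[2]):
                                    k = k0 + r
                                    if 0 <= i < h and 0 <= j < w and 0 <= k < bands:
                                        v = x[n, ch, i, j, k]
                                        if v > best:
                                            best = v
                                            barg = off
                                    off += 1
                        out[n, ch, oi, oj, ok] = best
                        arg[n, ch, oi, oj, ok] = barg
    return out, arg


@njit(cache=True)
def maxpool3d_backward(dy, arg, dims, pool, stride, pad_before):
    n_, c_, oh, ow, ob = dy.shape
    dx = np.zeros((n_, c_, dims[0], dims[1], dims[2]), dtype=dy.dtype)
    for n in range(n_):
        for ch in range(c_):
            for oi in range(oh):
                for oj in range(ow):
                    for ok in range(ob):
                        off = arg[n, ch, oi, oj, ok]
                        r = off % pool[2]
                        q = (off // pool[2]) % pool[1]
                        p = off // (pool[1] * pool[2])
                        i = oi * stride[0] - pad_before[0] + p
                        j = oj * stride[1] - pad_before[1] + q
                        k = ok * stride[2] - pad_before[2] + r
                        dx[n, ch, i, j, k] += dy[n, ch, oi, oj, ok]
    return dx


@njit(cache=True)
def maxpool2d_forward(x, pool, stride, pad_before, outs):
    n_, c_, h, w = x.shape
    oh, ow = outs
    out = np.empty((n_, c_, oh, ow), dtype=x.dtype)
    arg = np.zeros((n_, c_, oh, ow), dtype=np.int16)
    for n in range(n_):
        for ch in range(c_):
            for oi in range(oh):
                i0 = oi * stride[0] - pad_before[0]
                for oj in range(ow):
                    j0 = oj * stride[1] - pad_before[1]
                    best = -np.inf
                    barg = 0
                    off = 0
                    for p in range(pool[0]):
                        i = i0 + p
                        for q in range(pool[1]):
                            j = j0 + q
                            if 0 <= i < h and 0 <= j < w:
                                v = x[n, ch, i, j]
                                if v > best:
                                    best = v
                                    barg = off
                            off += 1
                    out[n, ch, oi, oj] = best
                    arg[n, ch, oi, oj] = barg
    return out, arg


@njit(cache=True)
def maxpool2d_backward(dy, arg, dims, pool, stride, pad_before):
    n_, c_, oh, ow = dy.shape
    dx = np.zeros((n_, c_, dims[0], dims[1]), dtype=dy.dtype)
    for n in range(n_):
        for ch in range(c_):
            for oi in range(oh):
                for oj in range(ow):
                    off = arg[n, ch, oi, oj]
                    q = off % pool[1]
                    p = off // pool[1]
                    i = oi * stride[0] - pad_before[0] + p
                    j = oj * stride[1] - pad_before[1] + q
                    dx[n, ch, i, j] += dy[n, ch, oi, oj]
    return dx
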