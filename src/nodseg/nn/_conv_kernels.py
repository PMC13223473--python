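"""JIT-compiled direct 3D convolution kernels.

The stride-1 dilated grouped convolutions the network uses are compute-bound
at small channel counts, so explicit loops with a contiguous innermost row
(the W axis) compiled by numba beat an im2col + GEMM formulation on one CPU
core.  Unit-dilation convolutions get a specialized kernel: with the tap
offset a compile-time stride the inner row loop vectorizes, which is worth
about 3x.  The autodiff layer falls back to im2col when numba is missing.

All kernels take the *padded* input ``xp`` of shape (N, Cin, Dp, Hp, Wp),
weights (Cout, Cin/groups, kd, kh, kw), and accumulate into a preallocated
zeroed output; ``cig``/``cog`` are channels per group on each side.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap(a[0]) if a and callable(a[0]) else wrap


@njit(cache=True, fastmath=True)
def _fwd_unit(xp, w, y, cig, cog):
    # (z, h) outer so the output row stays cache-resident while every tap
    # of every input channel accumulates into it in a single pass.
    n = xp.shape[0]
    ncout, oD, oH, oW = y.shape[1], y.shape[2], y.shape[3], y.shape[4]
    kd, kh, kw = w.shape[2], w.shape[3], w.shape[4]
    for ni in range(n):
        for co in range(ncout):
            g = co // cog
            for z in range(oD):
                for h in range(oH):
                    yrow = y[ni, co, z, h]
                    for ci_l in range(cig):
                        ci = g * cig + ci_l
                        for a in range(kd):
                            for b in range(kh):
                                xrow = xp[ni, ci, z + a, h + b]
                                for c in range(kw):
                                    wv = w[co, ci_l, a, b, c]
                                    for x in range(oW):
                                        yrow[x] += wv * xrow[x + c]
    return y


@njit(cache=True, fastmath=True)
def _fwd_dilated(xp, w, y, dd, dh, dw, cig, cog):
    n = xp.shape[0]
    ncout, oD, oH, oW = y.shape[1], y.shape[2], y.shape[3], y.shape[4]
    kd, kh, kw = w.shape[2], w.shape[3], w.shape[4]
    for ni in range(n):
        for co in range(ncout):
            g = co // cog
            for ci_l in range(cig):
                ci = g * cig + ci_l
                for a in range(kd):
                    for b in range(kh):
                        for z in range(oD):
                            zz = z + a * dd
                            for h in range(oH):
                                xrow = xp[ni, ci, zz, h + b * dh]
                                yrow = y[ni, co, z, h]
                                for c in range(kw):
                                    wv = w[co, ci_l, a, b, c]
                                    off = c * dw
                                    for x in range(oW):
                                        yrow[x] += wv * xrow[x + off]
    return y


@njit(cache=True, fastmath=True)
def _wgrad_unit(xp, gy, dwt, cig, cog):
    # single pass over the data per (co, ci) pair; all k^3 tap dot products
    # are formed from cache-resident rows.
    n = xp.shape[0]
    ncout, oD, oH, oW = gy.shape[1], gy.shape[2], gy.shape[3], gy.shape[4]
    kd, kh, kw = dwt.shape[2], dwt.shape[3], dwt.shape[4]
    for ni in range(n):
        for co in range(ncout):
            g = co // cog
            for ci_l in range(cig):
                ci = g * cig + ci_l
                for z in range(oD):
                    for h in range(oH):
                        gyrow = gy[ni, co, z, h]
                        for a in range(kd):
                            for b in range(kh):
                                xrow = xp[ni, ci, z + a, h + b]
                                for c in range(kw):
                                    acc = np.float32(0.0)
                                    for x in range(oW):
                                        acc += gyrow[x] * xrow[x + c]
                                    dwt[co, ci_l, a, b, c] += acc
    return dwt


@njit(cache=True, fastmath=True)
def _wgrad_dilated(xp, gy, dwt, dd, dh, dw, cig, cog):
    n = xp.shape[0]
    ncout, oD, oH, oW = gy.shape[1], gy.shape[2], gy.shape[3], gy.shape[4]
    kd, kh, kw = dwt.shape[2], dwt.shape[3], dwt.shape[4]
    for ni in range(n):
        for co in range(ncout):
            g = co // cog
            for ci_l in range(cig):
                ci = g * cig + ci_l
                for a in range(kd):
                    for b in range(kh):
                        for c in range(kw):
                            off = c * dw
                            acc = np.float32(0.0)
                            for z in range(oD):
                                zz = z + a * dd
                                for h in range(oH):
                                    gyrow = gy[ni, co, z, h]
                                    xrow = xp[ni, ci, zz, h + b * dh]
                                    for x in range(oW):
                                        acc += gyrow[x] * xrow[x + off]
                            dwt[co, ci_l, a, b, c] += acc
    return dwt


@njit(cache=True, fastmath=True)
def _fwd_unit_k3(xp, w, y, cig, cog):
    # fully fused width taps: three FMAs per output store
    n = xp.shape[0]
    ncout, oD, oH, oW = y.shape[1], y.shape[2], y.shape[3], y.shape[4]
    kd, kh = w.shape[2], w.shape[3]
    for ni in range(n):
        for co in range(ncout):
            g = co // cog
            for z in range(oD):
                for h in range(oH):
                    yrow = y[ni, co, z, h]
                    for ci_l in range(cig):
                        ci = g * cig + ci_l
                        for a in range(kd):
                            for b in range(kh):
                                xrow = xp[ni, ci, z + a, h + b]
                                w0 = w[co, ci_l, a, b, 0]
                                w1 = w[co, ci_l, a, b, 1]
                                w2 = w[co, ci_l, a, b, 2]
                                for x in range(oW):
                                    yrow[x] += (w0 * xrow[x]
                                                + w1 * xrow[x + 1]
                                                + w2 * xrow[x + 2])
    return y


@njit(cache=True, fastmath=True)
def _wgrad_unit_k3(xp, gy, dwt, cig, cog):
    n = xp.shape[0]
    ncout, oD, oH, oW = gy.shape[1], gy.shape[2], gy.shape[3], gy.shape[4]
    kd, kh = dwt.shape[2], dwt.shape[3]
    for ni in range(n):
        for co in range(ncout):
            g = co // cog
            for ci_l in range(cig):
                ci = g * cig + ci_l
                for z in range(oD):
                    for h in range(oH):
                        gyrow = gy[ni, co, z, h]
                        for a in range(kd):
                            for b in range(kh):
                                xrow = xp[ni, ci, z + a, h + b]
                                a0 = np.float32(0.0)
                                a1 = np.float32(0.0)
                                a2 = np.float32(0.0)
                                for x in range(oW):
                                    gv = gyrow[x]
                                    a0 += gv * xrow[x]
                                    a1 += gv * xrow[x + 1]
                                    a2 += gv * xrow[x + 2]
                                dwt[co, ci_l, a, b, 0] += a0
                                dwt[co, ci_l, a, b, 1] += a1
                                dwt[co, ci_l, a, b, 2] += a2
    return dwt


@njit(cache=True, fastmath=True)
def _fwd_unit_k7(xp, w, y, cig, cog):
    n = xp.shape[0]
    ncout, oD, oH, oW = y.shape[1], y.shape[2], y.shape[3], y.shape[4]
    kd, kh = w.shape[2], w.shape[3]
    for ni in range(n):
        for co in range(ncout):
            g = co // cog
            for z in range(oD):
                for h in range(oH):
                    yrow = y[ni, co, z, h]
                    for ci_l in range(cig):
                        ci = g * cig + ci_l
                        for a in range(kd):
                            for b in range(kh):
                                xrow = xp[ni, ci, z + a, h + b]
                                w0 = w[co, ci_l, a, b, 0]
                                w1 = w[co, ci_l, a, b, 1]
                                w2 = w[co, ci_l, a, b, 2]
                                w3 = w[co, ci_l, a, b, 3]
                                w4 = w[co, ci_l, a, b, 4]
                                w5 = w[co, ci_l, a, b, 5]
                                w6 = w[co, ci_l, a, b, 6]
                                for x in range(oW):
                                    yrow[x] += (w0 * xrow[x] + w1 * xrow[x + 1]
                                                + w2 * xrow[x + 2]
                                                + w3 * xrow[x + 3]
                                                + w4 * xrow[x + 4]
                                                + w5 * xrow[x + 5]
                                                + w6 * xrow[x + 6])
    return y


@njit(cache=True, fastmath=True)
def _wgrad_unit_k7(xp, gy, dwt, cig, cog):
    n = xp.shape[0]
    ncout, oD, oH, oW = gy.shape[1], gy.shape[2], gy.shape[3], gy.shape[4]
    kd, kh = dwt.shape[2], dwt.shape[3]
    for ni in range(n):
        for co in range(ncout):
            g = co // cog
            for ci_l in range(cig):
                ci = g * cig + ci_l
                for z in range(oD):
                    for h in range(oH):
                        gyrow = gy[ni, co, z, h]
                        for a in range(kd):
                            for b in range(kh):
                                xrow = xp[ni, ci, z + a, h + b]
                                a0 = np.float32(0.0)
                                a1 = np.float32(0.0)
                                a2 = np.float32(0.0)
                                a3 = np.float32(0.0)
                                a4 = np.float32(0.0)
                                a5 = np.float32(0.0)
                                a6 = np.float32(0.0)
                                for x in range(oW):
                                    gv = gyrow[x]
                                    a0 += gv * xrow[x]
                                    a1 += gv * xrow[x + 1]
                                    a2 += gv * xrow[x + 2]
                                    a3 += gv * xrow[x + 3]
                                    a4 += gv * xrow[x + 4]
                                    a5 += gv * xrow[x + 5]
                                    a6 += gv * xrow[x + 6]
                                dwt[co, ci_l, a, b, 0] += a0
                                dwt[co, ci_l, a, b, 1] += a1
                                dwt[co, ci_l, a, b, 2] += a2
                                dwt[co, ci_l, a, b, 3] += a3
                                dwt[co, ci_l, a, b, 4] += a4
                                dwt[co, ci_l, a, b, 5] += a5
                                dwt[co, ci_l, a, b, 6] += a6
    return dwt


def conv3d_fwd(xp, w, y, dd, dh, dw, cig, cog):
    if dd == dh == dw == 1:
        if w.shape[4] == 3:
            return _fwd_unit_k3(xp, w, y, cig, cog)
        if w.shape[4] == 7:
            return _fwd_unit_k7(xp, w, y, cig, cog)
        return _fwd_unit(xp, w, y, cig, cog)
    return _fwd_dilated(xp, w, y, dd, dh, dw, cig, cog)


def conv3d_wgrad(xp, gy, dwt, dd, dh, dw, cig, cog):
    if dd == dh == dw == 1:
        if dwt.shape[4] == 3:
            return _wgrad_unit_k3(xp, gy, dwt, cig, cog)
        if dwt.shape[4] == 7:
            return _wgrad_unit_k7(xp, gy, dwt, cig, cog)
        return _wgrad_unit(xp, gy, dwt, cig, cog)
    return _wgrad_dilated(xp, gy, dwt, dd, dh, dw, cig, cog)
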