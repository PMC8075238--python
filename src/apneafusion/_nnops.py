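"""Low-level array kernels for the CNN: im2col packing and 2x2 max pooling.

Convolutions are evaluated as im2col + BLAS GEMM. The patch packing and
col2im scatter are the memory-bound steps, so they are JIT-compiled;
tensors are channels-last (N, H, W, C) so the innermost copies are
contiguous.
"""

from __future__ import annotations

from numba import njit


@njit(cache=True)
def pack_cols3(xp, cols):
    """Pack 3x3 patches of padded input xp (N, H+2, W+2, C) into cols (N, H, W, 9, C)."""
    n_, h_, w_ = cols.shape[0], cols.shape[1], cols.shape[2]
    c_ = xp.shape[3]
    for n in range(n_):
        for y in range(h_):
            for dy in range(3):
                src = xp[n, y + dy]
                for x in range(w_):
                    for dx in range(3):
                        row = src[x + dx]
                        dst = cols[n, y, x, dy * 3 + dx]
                        for c in range(c_):
                            dst[c] = row[c]


@njit(cache=True)
def unpack_cols3_add(dcols, dxp):
    """Scatter-add cols gradients (N, H, W, 9, C) back into padded dxp (N, H+2, W+2, C)."""
    n_, h_, w_ = dcols.shape[0], dcols.shape[1], dcols.shape[2]
    c_ = dxp.shape[3]
    for n in range(n_):
        for y in range(h_):
            for dy in range(3):
                dst = dxp[n, y + dy]
                for x in range(w_):
                    for dx in range(3):
                        d = dst[x + dx]
                        s = dcols[n, y, x, dy * 3 + dx]
                        for c in range(c_):
                            d[c] += s[c]


@njit(cache=True)
def maxpool2_fwd(x, out, arg):
    """2x2 stride-2 max pooling (channels-last); ``arg`` stores the winner (0..3)."""
    n_, ho, wo, c_ = out.shape
    for n in range(n_):
        for y in range(ho):
            r0 = x[n, 2 * y]
            r1 = x[n, 2 * y + 1]
            for xx in range(wo):
                a0 = r0[2 * xx]
                a1 = r0[2 * xx + 1]
                a2 = r1[2 * xx]
                a3 = r1[2 * xx + 1]
                for c in range(c_):
                    v = a0[c]
                    k = 0
                    if a1[c] > v:
                        v = a1[c]
                        k = 1
                    if a2[c] > v:
                        v = a2[c]
                        k = 2
                    if a3[c] > v:
                        v = a3[c]
                        k = 3
                    out[n, y, xx, c] = v
                    arg[n, y, xx, c] = k


@njit(cache=True)
def maxpool2_bwd(dout, arg, dx):
    """Route pooled gradients back to the argmax positions; dx must be zeroed."""
    n_, ho, wo, c_ = dout.shape
    for n in range(n_):
        for y in range(ho):
            for xx in range(wo):
                for c in range(c_):
                    k = arg[n, y, xx, c]
                    dy = k // 2
                    dxx = k % 2
                    dx[n, 2 * y + dy, 2 * xx + dxx, c] += dout[n, y, xx, c]
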