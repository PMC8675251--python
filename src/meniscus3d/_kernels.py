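"""Numba-jitted gather/scatter kernels for the 3D convolution.

The im2col gather and col2im scatter-add touch every input voxel once per
kernel tap; a jitted loop keeps them memory-bound instead of paying numpy's
per-element iterator overhead on sliced 8-D views.  Column layout is channel
-major then kernel offsets, matching ``weight.reshape(F, C*kd*kh*kw)``.
"""

from __future__ import annotations

from numba import njit


@njit(fastmath=True)
def gather3d(xp, cols, od, oh, ow, kd, kh, kw, sd, sh, sw, dd, dh, dw):
    N, C, D, H, W = xp.shape
    for n in range(N):
        for z in range(od):
            for y in range(oh):
                for x in range(ow):
                    row = ((n * od + z) * oh + y) * ow + x
                    col = 0
                    for c in range(C):
                        for a in range(kd):
                            iz = z * sd + a * dd
                            for b in range(kh):
                                line = xp[n, c, iz, y * sh + b * dh]
                                x0 = x * sw
                                for e in range(kw):
                                    cols[row, col] = line[x0 + e * dw]
                                    col += 1


@njit(fastmath=True)
def scatter3d(dxp, dcols, od, oh, ow, kd, kh, kw, sd, sh, sw, dd, dh, dw):
    N, C, D, H, W = dxp.shape
    for n in range(N):
        for z in range(od):
            for y in range(oh):
                for x in range(ow):
                    row = ((n * od + z) * oh + y) * ow + x
                    col = 0
                    for c in range(C):
                        for a in range(kd):
                            iz = z * sd + a * dd
                            for b in range(kh):
                                line = dxp[n, c, iz, y * sh + b * dh]
                                x0 = x * sw
                                for e in range(kw):
                                    line[x0 + e * dw] += dcols[row, col]
                                    col += 1
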