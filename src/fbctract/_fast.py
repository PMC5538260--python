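"""Numba-accelerated kernel evaluation.

Scalar port of :func:`fbctract.se3_kernel.eval_kernel_many`; the numpy
implementation remains the reference and the two are pinned together by
tests.  Falls back transparently when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco


@njit(cache=False, fastmath=False)
def _base_density(dx, dy, dz, sx, sy, sz, tx, ty, tz, d_long, d_ang, t, norm):
    # rotate (d, t) into the frame taking the source orientation to +e_z
    c = sz
    rx, ry = sy, -sx
    if 1.0 + c > 1e-12:
        fac = 1.0 / (1.0 + c)
        rdd = rx * dx + ry * dy
        ddx = c * dx + ry * dz + fac * rdd * rx
        ddy = c * dy - rx * dz + fac * rdd * ry
        ddz = c * dz + rx * dy - ry * dx
        rdt = rx * tx + ry * ty
        nnx = c * tx + ry * tz + fac * rdt * rx
        nny = c * ty - rx * tz + fac * rdt * ry
        nnz = c * tz + rx * ty - ry * tx
    else:  # source ~ -e_z: pi rotation about x
        ddx, ddy, ddz = dx, -dy, -dz
        nnx, nny, nnz = tx, -ty, -tz

    nz = nnz
    if nz > 1.0:
        nz = 1.0
    elif nz < -1.0:
        nz = -1.0
    theta = np.arccos(nz)
    s = np.sqrt(nnx * nnx + nny * nny)
    if s > 1e-12:
        scale = theta / s
        ux, uy = nnx / s, nny / s
    else:
        scale = 1.0
        ux, uy = 1.0, 0.0
    wx = -nny * scale
    wy = nnx * scale

    th2 = theta * theta
    if theta < 1e-4:
        kappa = 1.0 / 12.0 + th2 / 720.0
    else:
        half = 0.5 * theta
        kappa = (1.0 - half * np.cos(half) / np.sin(half)) / th2

    c1x = wy * ddz
    c1y = -wx * ddz
    c1z = wx * ddy - wy * ddx
    c2x = wy * c1z
    c2y = -wx * c1z
    c2z = wx * c1y - wy * c1x
    c1 = ddx - 0.5 * c1x + kappa * c2x
    c2 = ddy - 0.5 * c1y + kappa * c2y
    c3 = ddz - 0.5 * c1z + kappa * c2z

    c_par = c1 * ux + c2 * uy
    c_perp = -c1 * uy + c2 * ux
    base = d_long * d_ang * t * t / 3.0 + d_ang * t * c3 * c3 / 6.0
    sig_par2 = base + d_long * t * th2 / 6.0
    sig_perp2 = base

    val = np.exp(-c3 * c3 / (4.0 * d_long * t) - th2 / (4.0 * d_ang * t))
    if theta > 1e-6:
        st = np.sin(min(theta, np.pi - 1e-9))
        if st < 1e-12:
            st = 1e-12
        val *= np.sqrt(theta / st)
    val *= np.exp(-c_par * c_par / (2.0 * sig_par2) - c_perp * c_perp / (2.0 * sig_perp2)) / (
        2.0 * np.pi * np.sqrt(sig_par2 * sig_perp2)
    )
    return norm * val


@njit(cache=False, fastmath=False)
def _eval_sym_arrays(dy, n_src, n_dst, d_long, d_ang, t, norm, out):
    for i in range(dy.shape[0]):
        a = _base_density(
            dy[i, 0], dy[i, 1], dy[i, 2],
            n_src[i, 0], n_src[i, 1], n_src[i, 2],
            n_dst[i, 0], n_dst[i, 1], n_dst[i, 2],
            d_long, d_ang, t, norm,
        )
        b = _base_density(
            dy[i, 0], dy[i, 1], dy[i, 2],
            n_src[i, 0], n_src[i, 1], n_src[i, 2],
            -n_dst[i, 0], -n_dst[i, 1], -n_dst[i, 2],
            d_long, d_ang, t, norm,
        )
        out[i] = 0.5 * (a + b)


def eval_kernel_fast(dy: np.ndarray, n_src: np.ndarray, n_dst: np.ndarray, params) -> np.ndarray:
    """Antipodally symmetrized kernel values; numba-compiled when available."""
    dy = np.ascontiguousarray(dy, dtype=np.float64)
    n_src = np.ascontiguousarray(n_src, dtype=np.float64)
    n_dst = np.ascontiguousarray(n_dst, dtype=np.float64)
    out = np.empty(len(dy))
    _eval_sym_arrays(dy, n_src, n_dst, params.d_long, params.d_ang, params.t_diff,
                     params.normalization(), out)
    return out
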