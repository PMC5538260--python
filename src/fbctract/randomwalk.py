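"""Monte-Carlo simulation of the hypo-elliptic random walk.

Walkers start at the origin oriented along +z.  In every small time step they
move forward or backward along their current orientation and reorient by a
small random rotation, but never move sideways.  The empirical end-pose
distribution of many walkers is an independent estimate of the
Brownian-motion kernel and serves as the validation oracle for
:func:`fbctract.se3_kernel.eval_kernel`.
"""

from __future__ import annotations

import numpy as np

from .se3_kernel import KernelParams, eval_kernel_many

__all__ = ["simulate_walkers", "pose_histogram", "kernel_bin_masses"]


def simulate_walkers(
    params: KernelParams,
    n_walkers: int,
    n_steps: int = 140,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama simulation of the walk; returns end (positions, orientations).

    Per step of length dt = t_diff/n_steps the position increment is
    n * N(0, 2*d_long*dt) (forward/backward only) and the orientation gets a
    tangent-plane Gaussian kick with per-axis variance 2*d_ang*dt, then is
    renormalized (Brownian motion on S^2 in the small-step limit).
    """
    if rng is None:
        rng = np.random.default_rng()
    dt = params.t_diff / n_steps
    sig_pos = np.sqrt(2.0 * params.d_long * dt)
    sig_ang = np.sqrt(2.0 * params.d_ang * dt)
    y = np.zeros((n_walkers, 3))
    n = np.zeros((n_walkers, 3))
    n[:, 2] = 1.0
    for _ in range(n_steps):
        y += n * (sig_pos * rng.standard_normal((n_walkers, 1)))
        kick = sig_ang * rng.standard_normal((n_walkers, 3))
        kick -= n * np.sum(kick * n, axis=1, keepdims=True)  # tangent projection
        n += kick
        n /= np.linalg.norm(n, axis=1, keepdims=True)
    return y, n


def pose_histogram(
    positions: np.ndarray,
    orientations: np.ndarray,
    z_edges: np.ndarray,
    rho_edges: np.ndarray,
    beta_edges: np.ndarray,
) -> np.ndarray:
    """Bin end poses into (axial z, cylindrical radius rho, polar angle beta) cells.

    The histogram is folded the same way the kernel is symmetrized: the polar
    angle is antipodally collapsed (beta = arccos|n_z|) and the axial
    coordinate is averaged with its mirror image (a walker started at -e_z is
    the pi-rotation image of one started at +e_z), so the folded masses are
    directly comparable to the antipodally symmetrized kernel.
    """
    z = positions[:, 2]
    rho = np.hypot(positions[:, 0], positions[:, 1])
    beta = np.arccos(np.clip(np.abs(orientations[:, 2]), 0.0, 1.0))
    sample = np.stack([z, rho, beta], axis=1)
    h, _ = np.histogramdd(sample, bins=(z_edges, rho_edges, beta_edges))
    return 0.5 * (h + h[::-1])


def kernel_bin_masses(
    params: KernelParams,
    z_edges: np.ndarray,
    rho_edges: np.ndarray,
    beta_edges: np.ndarray,
    *,
    n_quad: int = 3,
    n_quad_azimuth: int = 24,
) -> np.ndarray:
    """Kernel-predicted mass in each (z, rho, beta) cell, by midpoint quadrature.

    By joint axial symmetry the source azimuth is fixed at zero and the
    relative azimuth integrated; the cell measure contributes
    2*pi*rho drho dz for position and sin(beta) dbeta dphi for orientation.
    """
    nz, nr, nb = len(z_edges) - 1, len(rho_edges) - 1, len(beta_edges) - 1
    ez = np.array([0.0, 0.0, 1.0])
    phis = (np.arange(n_quad_azimuth) + 0.5) / n_quad_azimuth * 2.0 * np.pi
    mid = (np.arange(n_quad) + 0.5) / n_quad
    out = np.zeros((nz, nr, nb))
    for iz in range(nz):
        zq = z_edges[iz] + mid * (z_edges[iz + 1] - z_edges[iz])
        wz = (z_edges[iz + 1] - z_edges[iz]) / n_quad
        for ir in range(nr):
            rq = rho_edges[ir] + mid * (rho_edges[ir + 1] - rho_edges[ir])
            wr = rq * (rho_edges[ir + 1] - rho_edges[ir]) / n_quad  # rho drho
            for ib in range(nb):
                bq = beta_edges[ib] + mid * (beta_edges[ib + 1] - beta_edges[ib])
                wb = np.sin(bq) * (beta_edges[ib + 1] - beta_edges[ib]) / n_quad
                Z, R, B, P = np.meshgrid(zq, rq, bq, phis, indexing="ij")
                m = Z.size
                pos = np.stack([R.ravel(), np.zeros(m), Z.ravel()], axis=1)
                n_dst = np.stack(
                    [np.sin(B.ravel()) * np.cos(P.ravel()),
                     np.sin(B.ravel()) * np.sin(P.ravel()),
                     np.cos(B.ravel())],
                    axis=1,
                )
                src = np.broadcast_to(ez, pos.shape)
                vals = eval_kernel_many(pos, src, n_dst, params, check_units=False).reshape(Z.shape)
                w = (
                    wz
                    * wr[None, :, None, None]
                    * wb[None, None, :, None]
                    * (2.0 * np.pi / n_quad_azimuth)
                )
                out[iz, ir, ib] = 2.0 * np.pi * np.sum(w * vals)
    return out
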