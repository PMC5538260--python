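"""Brownian-motion kernel on the space of positions and orientations.

The coherence measure rests on a contour-enhancement process on the rigid-body
motion group SE(3), projected to R^3 x S^2: a walker at pose (y, n) diffuses
forward/backward along its orientation n (longitudinal diffusivity ``d_long``)
and reorients by Brownian motion on the sphere (angular diffusivity ``d_ang``),
but cannot move sideways.  The transition density after time ``t_diff`` is the
kernel used for streamline density estimation.

The density is hypo-elliptic: sideways displacements are only reachable through
the commutator of translation and rotation generators, so for a fixed
displacement magnitude the kernel is largest along the orientation axis and
decays much faster perpendicular to it.

``eval_kernel`` implements a Gaussian-type estimate of this heat kernel in
exponential (logarithmic) coordinates of SE(3), symmetrized over antipodal
orientation flips so that the value is independent of streamline head/tail
convention.  The estimate is validated against a Monte-Carlo simulation of the
defining random walk (see :mod:`fbctract.randomwalk`).
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path

import numpy as np

__all__ = [
    "KernelParams",
    "KernelTable",
    "eval_kernel",
    "eval_kernel_many",
    "build_table",
    "lookup",
    "sphere_directions",
]

_EZ = np.array([0.0, 0.0, 1.0])

# Sideways (commutator) variances in exponential coordinates, conditional on
# the reachable coordinates: lateral displacement is the stochastic integral
# of the tilt path against the forward motion, so its conditional variance
# grows with the final tilt and the axial excursion.  The coefficients are the
# exact second moments of the defining walk (Brownian-bridge conditioning);
# see docs/methods.md.  Validated against the Monte-Carlo walker histogram.
_LAT_BASE = 1.0 / 3.0   # * d_long * d_ang * t^2
_LAT_TILT = 1.0 / 6.0   # * d_long * t * theta^2   (axis along the tilt azimuth)
_LAT_AXIAL = 1.0 / 6.0  # * d_ang * t * c3^2       (both lateral axes)

# Memory cap for lookup tables (bytes); build_table refuses larger allocations.
DEFAULT_TABLE_CAP_BYTES = 2 << 30


@dataclasses.dataclass(frozen=True)
class KernelParams:
    """Parameters of the hypo-elliptic Brownian-motion kernel.

    Attributes
    ----------
    d_long : float
        Longitudinal diffusivity in mm^2 per unit time: variance rate of the
        forward/backward motion along the orientation axis.
    d_ang : float
        Angular diffusivity in rad^2 per unit time: variance rate (per tangent
        axis) of the Brownian reorientation on the sphere.
    t_diff : float
        Total diffusion time (unitless scale); together with the diffusivities
        it sets the spatial reach ~sqrt(2*d_long*t_diff) and angular spread
        ~sqrt(2*d_ang*t_diff) of the kernel.
    """

    d_long: float = 1.0
    d_ang: float = 0.04
    t_diff: float = 1.4

    def __post_init__(self) -> None:
        for name in ("d_long", "d_ang", "t_diff"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"KernelParams.{name} must be strictly positive, got {v!r}")

    def normalization(self) -> float:
        """Prefactor of the reachable-coordinate Gaussians (the lateral
        factor carries its own pose-dependent normalization).

        RFBC is a ratio of kernel sums, so any global constant cancels; the
        normalization only keeps the kernel close to a probability density.
        """
        t = self.t_diff
        ax = np.sqrt(4.0 * np.pi * self.d_long * t)          # axial width
        ang = 4.0 * np.pi * self.d_ang * t                   # solid-angle mass
        return 1.0 / (ax * ang)


def _as_unit(v: np.ndarray, name: str, atol: float = 1e-6) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    norms = np.linalg.norm(v, axis=-1)
    if not np.allclose(norms, 1.0, atol=atol):
        raise ValueError(f"{name} must be unit vectors (|norm - 1| <= {atol})")
    return v


def _rotate_to_z(n_src: np.ndarray, vecs: np.ndarray) -> np.ndarray:
    """Apply the minimal rotation taking each n_src to +e_z to each row of vecs.

    Rodrigues form of the rotation with axis n_src x e_z; the axial (twist)
    freedom is irrelevant because the kernel modulus is axially isotropic.
    """
    c = n_src[:, 2]                       # n_src . e_z
    # r = n_src x e_z
    rx = n_src[:, 1]
    ry = -n_src[:, 0]
    rdotv = rx * vecs[:, 0] + ry * vecs[:, 1]
    # r x v with r = (rx, ry, 0)
    cross = np.empty_like(vecs)
    cross[:, 0] = ry * vecs[:, 2]
    cross[:, 1] = -rx * vecs[:, 2]
    cross[:, 2] = rx * vecs[:, 1] - ry * vecs[:, 0]
    denom = 1.0 + c
    safe = denom > 1e-12
    fac = np.where(safe, rdotv / np.where(safe, denom, 1.0), 0.0)
    out = c[:, None] * vecs + cross + fac[:, None] * np.stack([rx, ry, np.zeros_like(rx)], axis=1)
    # n_src ~ -e_z: use the pi-rotation about x, v -> (vx, -vy, -vz)
    if not np.all(safe):
        flip = ~safe
        out[flip, 0] = vecs[flip, 0]
        out[flip, 1] = -vecs[flip, 1]
        out[flip, 2] = -vecs[flip, 2]
    return out


def _density(delta: np.ndarray, n_rel: np.ndarray, params: KernelParams) -> np.ndarray:
    """Kernel density of the relative pose g = (delta, R_n) in the source frame
    (source at the origin oriented along +e_z).

    Gaussian estimate in exponential coordinates c1..c5 of g (the axial c6
    vanishes for the minimal rotation): the reachable coordinates carry the
    direct diffusion variances (2*d_long*t axially, 2*d_ang*t per angular
    axis, with the sphere-volume correction sqrt(theta/sin theta)); the
    forbidden sideways coordinates are Gaussian with the conditional
    commutator variances declared above, split along/across the tilt
    azimuth.  Exponential coordinates decorrelate the axial-lateral cross
    moments, so the quadratic form is diagonal in this frame.
    """
    nz = np.clip(n_rel[:, 2], -1.0, 1.0)
    theta = np.arccos(nz)
    s = np.sqrt(np.maximum(n_rel[:, 0] ** 2 + n_rel[:, 1] ** 2, 0.0))
    # rotation vector omega = theta * (ez x n)/|ez x n|, in-plane
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(s > 1e-12, theta / np.where(s > 1e-12, s, 1.0), 1.0)
    wx = -n_rel[:, 1] * scale
    wy = n_rel[:, 0] * scale

    # c^(1) = V^{-1}(omega) delta,  V^{-1} = I - 1/2 [w]x + kappa(theta) [w]x^2
    th2 = theta * theta
    small = theta < 1e-4
    half = 0.5 * theta
    with np.errstate(invalid="ignore", divide="ignore"):
        cot = np.where(small, 1.0, np.cos(half) / np.where(small, 1.0, np.sin(half)))
        kappa = np.where(
            small,
            1.0 / 12.0 + th2 / 720.0,
            (1.0 - half * cot) / np.where(small, 1.0, th2),
        )

    dx, dy_, dz = delta[:, 0], delta[:, 1], delta[:, 2]
    # w x d with w = (wx, wy, 0)
    c1x = wy * dz
    c1y = -wx * dz
    c1z = wx * dy_ - wy * dx
    # w x (w x d)
    c2x = wy * c1z
    c2y = -wx * c1z
    c2z = wx * c1y - wy * c1x
    c1 = dx - 0.5 * c1x + kappa * c2x
    c2 = dy_ - 0.5 * c1y + kappa * c2y
    c3 = dz - 0.5 * c1z + kappa * c2z

    t = params.t_diff
    # lateral coordinates along/across the tilt azimuth; at zero tilt the
    # variances coincide and any orthonormal split works
    degen = s <= 1e-12
    s_safe = np.where(degen, 1.0, s)
    ux = np.where(degen, 1.0, n_rel[:, 0] / s_safe)
    uy = np.where(degen, 0.0, n_rel[:, 1] / s_safe)
    c_par = c1 * ux + c2 * uy
    c_perp = -c1 * uy + c2 * ux
    base = _LAT_BASE * params.d_long * params.d_ang * t * t + _LAT_AXIAL * params.d_ang * t * c3 * c3
    sig_par2 = base + _LAT_TILT * params.d_long * t * th2
    sig_perp2 = base

    val = np.exp(-c3 * c3 / (4.0 * params.d_long * t) - th2 / (4.0 * params.d_ang * t))
    # sphere-volume (Jacobian) correction of the angular Gaussian
    sin_th = np.maximum(np.sin(np.minimum(theta, np.pi - 1e-9)), 1e-12)
    val *= np.sqrt(np.where(theta > 1e-6, theta / sin_th, 1.0))
    val *= np.exp(-c_par * c_par / (2.0 * sig_par2) - c_perp * c_perp / (2.0 * sig_perp2)) / (
        2.0 * np.pi * np.sqrt(sig_par2 * sig_perp2)
    )
    return params.normalization() * val


def _eval_base(dy: np.ndarray, n_src: np.ndarray, n_dst: np.ndarray, params: KernelParams) -> np.ndarray:
    delta = _rotate_to_z(n_src, dy)
    n_rel = _rotate_to_z(n_src, n_dst)
    return _density(delta, n_rel, params)


def eval_kernel_many(
    dy: np.ndarray,
    n_src: np.ndarray,
    n_dst: np.ndarray,
    params: KernelParams,
    *,
    check_units: bool = True,
) -> np.ndarray:
    """Vectorized kernel evaluation on arrays of relative poses.

    Parameters are broadcast row-wise: all inputs must have shape (M, 3).
    The value is averaged over the four antipodal flips of the two
    orientation arguments, making it independent of streamline direction
    conventions.
    """
    dy = np.atleast_2d(np.asarray(dy, dtype=float))
    n_src = np.atleast_2d(np.asarray(n_src, dtype=float))
    n_dst = np.atleast_2d(np.asarray(n_dst, dtype=float))
    if check_units:
        n_src = _as_unit(n_src, "n_src")
        n_dst = _as_unit(n_dst, "n_dst")
    # the two source flips duplicate the two destination flips (joint
    # antipodal inversion is a symmetry of the walk), so two terms suffice
    return 0.5 * (
        _eval_base(dy, n_src, n_dst, params) + _eval_base(dy, n_src, -n_dst, params)
    )


def eval_kernel(dy, n_src, n_dst, params: KernelParams) -> float:
    """Kernel density at destination pose (dy, n_dst) relative to a source at
    the origin with orientation n_src.  Nonnegative, left-invariant under
    rigid motions, symmetric under antipodal orientation flips."""
    return float(eval_kernel_many(dy, n_src, n_dst, params)[0])


# ---------------------------------------------------------------------------
# sphere tessellation


def sphere_directions(count: int = 162) -> np.ndarray:
    """Unit directions from an icosahedral tessellation, antipodally collapsed.

    ``count`` is the full two-hemisphere vertex count (12, 42, 162 or 642);
    the returned array holds one representative per antipodal pair
    (count/2 + 1 directions), each with nonnegative z (ties broken toward
    positive x then y).
    """
    from trimesh.creation import icosphere

    subdiv = {12: 0, 42: 1, 162: 2, 642: 3}.get(count)
    if subdiv is None:
        raise ValueError(f"orientation count must be one of 12, 42, 162, 642; got {count}")
    verts = np.asarray(icosphere(subdivisions=subdiv, radius=1.0).vertices, dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    # canonical antipodal representative
    key = verts.copy()
    flip = (key[:, 2] < -1e-12) | (
        (np.abs(key[:, 2]) <= 1e-12) & ((key[:, 0] < -1e-12) | ((np.abs(key[:, 0]) <= 1e-12) & (key[:, 1] < 0)))
    )
    key[flip] *= -1.0
    uniq = np.unique(np.round(key, decimals=9), axis=0)
    uniq /= np.linalg.norm(uniq, axis=1, keepdims=True)
    return uniq


def nearest_direction(dirs: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Index of the antipodally-nearest tessellation direction for each row of n."""
    n = np.atleast_2d(n)
    return np.argmax(np.abs(n @ dirs.T), axis=1)


# ---------------------------------------------------------------------------
# lookup tables


class KernelTable:
    """Precomputed kernel values on a relative-pose grid.

    Values are stored for every (spatial grid node, source direction,
    destination direction) with directions from an antipodally-collapsed
    icosahedral tessellation.  Lookups use nearest-neighbor assignment in
    orientation and trilinear interpolation in space.
    """

    def __init__(self, params: KernelParams, half_width: float, spacing: float,
                 dirs: np.ndarray, values: np.ndarray):
        self.params = params
        self.half_width = float(half_width)
        self.spacing = float(spacing)
        self.dirs = np.asarray(dirs, dtype=float)
        self.values = values
        self.axis = np.arange(-self.half_width, self.half_width + 0.5 * self.spacing, self.spacing)
        if values.shape != (len(self.axis),) * 3 + (len(dirs), len(dirs)):
            raise ValueError("table value array shape inconsistent with grid spec")

    def save(self, path) -> None:
        """Serialize to a single self-describing array container (.npz)."""
        path = Path(path)
        buf = io.BytesIO()
        np.savez(
            buf,
            d_long=self.params.d_long,
            d_ang=self.params.d_ang,
            t_diff=self.params.t_diff,
            half_width=self.half_width,
            spacing=self.spacing,
            dirs=self.dirs,
            values=self.values,
        )
        path.write_bytes(buf.getvalue())

    @classmethod
    def load(cls, path) -> "KernelTable":
        with np.load(Path(path)) as z:
            params = KernelParams(float(z["d_long"]), float(z["d_ang"]), float(z["t_diff"]))
            return cls(params, float(z["half_width"]), float(z["spacing"]),
                       z["dirs"], z["values"])


def build_table(
    params: KernelParams,
    half_width: float = 6.0,
    spacing: float = 1.0,
    orientation_count: int = 162,
    *,
    max_bytes: int = DEFAULT_TABLE_CAP_BYTES,
) -> KernelTable:
    """Tabulate the kernel over a cubic grid of relative positions and a
    tessellated set of orientations.

    Raises before allocation if the table would exceed ``max_bytes``.
    """
    if not (half_width >= spacing > 0):
        raise ValueError("require half_width >= spacing > 0")
    if orientation_count < 12:
        raise ValueError("orientation_count must be >= 12")
    dirs = sphere_directions(orientation_count)
    axis = np.arange(-half_width, half_width + 0.5 * spacing, spacing)
    g = len(axis)
    k = len(dirs)
    nbytes = g ** 3 * k * k * 8
    if nbytes > max_bytes:
        raise MemoryError(
            f"kernel table would need {nbytes / 2**20:.0f} MiB "
            f"({g}^3 spatial nodes x {k}^2 direction pairs), cap is {max_bytes / 2**20:.0f} MiB"
        )
    from ._fast import eval_kernel_fast

    xx, yy, zz = np.meshgrid(axis, axis, axis, indexing="ij")
    grid = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    m = len(grid)
    values = np.empty((g, g, g, k, k))
    dst = np.repeat(dirs, m, axis=0)  # varies slowest over j
    dy = np.tile(grid, (k, 1))
    for i in range(k):
        src = np.ascontiguousarray(np.broadcast_to(dirs[i], (m * k, 3)))
        vals = eval_kernel_fast(dy, src, dst, params)
        values[:, :, :, i, :] = vals.reshape(k, g, g, g).transpose(1, 2, 3, 0)
    return KernelTable(params, half_width, spacing, dirs, values)


def lookup(table: KernelTable, dy, n_src, n_dst) -> np.ndarray:
    """Interpolated table lookup: nearest orientation, trilinear in space.

    Spatial interpolation acts on log-values (geometric interpolation):
    the kernel spans many orders of magnitude across one grid cell, and
    interpolating the exponent keeps the *relative* error bounded where
    arithmetic interpolation of the raw values can be off by orders of
    magnitude.  Exact at grid nodes.  Raises if any displacement falls
    outside the table's spatial extent; callers are expected to cull
    far-away pairs first.
    """
    dy = np.atleast_2d(np.asarray(dy, dtype=float))
    n_src = np.atleast_2d(np.asarray(n_src, dtype=float))
    n_dst = np.atleast_2d(np.asarray(n_dst, dtype=float))
    hw, sp = table.half_width, table.spacing
    if np.any(np.abs(dy) > hw + 1e-9):
        raise ValueError("relative position outside the kernel table grid; cull to the cutoff first")
    i_src = nearest_direction(table.dirs, n_src)
    i_dst = nearest_direction(table.dirs, n_dst)
    # fractional grid coordinates
    f = np.clip((dy + hw) / sp, 0.0, len(table.axis) - 1 - 1e-12)
    i0 = f.astype(int)
    w = f - i0
    acc = np.zeros(len(dy))
    vals = table.values
    with np.errstate(divide="ignore"):
        for bx in (0, 1):
            wx = np.where(bx, w[:, 0], 1.0 - w[:, 0])
            for by in (0, 1):
                wy = np.where(by, w[:, 1], 1.0 - w[:, 1])
                for bz in (0, 1):
                    wz = np.where(bz, w[:, 2], 1.0 - w[:, 2])
                    corner = vals[
                        np.minimum(i0[:, 0] + bx, len(table.axis) - 1),
                        np.minimum(i0[:, 1] + by, len(table.axis) - 1),
                        np.minimum(i0[:, 2] + bz, len(table.axis) - 1),
                        i_src,
                        i_dst,
                    ]
                    # floor keeps 0-weight corners from producing 0 * -inf
                    acc += wx * wy * wz * np.log(np.maximum(corner, 1e-300))
    return np.exp(acc)
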