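"""Fiber-to-bundle coherence (FBC) scoring.

For every point of every lifted streamline, the FBC is the kernel-density
mass contributed by the points of all *other* streamlines under the
Brownian-motion kernel.  A streamline's score is the minimum window-averaged
FBC along its length (AFBC^alpha), normalized by the bundle-wide average FBC
(AFBC(Gamma)) to give the relative FBC:

    RFBC^alpha(gamma_i, Gamma) = AFBC^alpha(gamma_i, Gamma) / AFBC(Gamma)

Streamlines with RFBC below a threshold epsilon are removed as spurious.
Scores are computed once on the full bundle; thresholding never re-scores,
so the sweep over epsilon acts on fixed scores.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._fast import eval_kernel_fast
from .se3_kernel import KernelParams, KernelTable, lookup
from .tract_model import Bundle, lift, resample

__all__ = [
    "FBCProfile",
    "RFBCScores",
    "compute_fbc",
    "afbc_window",
    "afbc_bundle",
    "rfbc",
    "threshold",
    "DEFAULT_CUTOFF",
    "DEFAULT_ALPHA",
    "DEFAULT_STEP",
]

DEFAULT_CUTOFF = 6.0  # mm; contributions beyond this distance are culled
DEFAULT_ALPHA = 2.0   # mm; sliding-window length
DEFAULT_STEP = 0.2    # mm; point spacing the window length assumes

_PAIR_CHUNK = 1_000_000


@dataclasses.dataclass(frozen=True)
class FBCProfile:
    """Per-point FBC values, one array per streamline (aligned with indices)."""

    indices: np.ndarray
    values: list

    def __post_init__(self):
        if len(self.indices) != len(self.values):
            raise ValueError("one value array per streamline required")
        for v in self.values:
            if np.any(np.asarray(v) < 0):
                raise ValueError("FBC values must be nonnegative")


@dataclasses.dataclass(frozen=True)
class RFBCScores:
    """Per-streamline AFBC^alpha and RFBC plus the bundle AFBC."""

    alpha: float
    window_points: int
    indices: np.ndarray
    afbc_alpha: np.ndarray
    rfbc: np.ndarray
    bundle_afbc: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"streamline_index": self.indices, "rfbc": self.rfbc, "afbc_alpha": self.afbc_alpha}
        )


def _lift_bundle(bundle: Bundle, step: float | None):
    lifted = []
    for s in bundle:
        if step is not None:
            s = resample(s, step)
        lifted.append(lift(s))
    return lifted


def compute_fbc(
    bundle: Bundle,
    kernel: KernelParams | KernelTable,
    cutoff: float = DEFAULT_CUTOFF,
    *,
    step: float | None = None,
    subsample: int = 1,
) -> FBCProfile:
    """Per-point kernel density along every streamline.

    FBC_i^k sums the kernel over all points of all other streamlines
    (self-contributions are excluded, so a lone streamline scores zero).
    Pairs farther apart than ``cutoff`` are culled with a KD-tree.  With
    ``subsample`` = m > 1 only every m-th point acts as a density source
    (all points remain evaluation targets); RFBC is stable under this since
    the same thinning enters numerator and denominator.
    """
    if len(bundle) == 0:
        raise ValueError("bundle is empty")
    if subsample < 1:
        raise ValueError("subsample must be >= 1")
    table = kernel if isinstance(kernel, KernelTable) else None
    if table is not None and cutoff > table.half_width + 1e-9:
        raise ValueError(
            f"cutoff {cutoff} mm exceeds the kernel table half-width {table.half_width} mm"
        )
    params = table.params if table is not None else kernel

    lifted = _lift_bundle(bundle, step)
    counts = np.array([len(ls) for ls in lifted])
    pts = np.concatenate([ls.points for ls in lifted])
    tans = np.concatenate([ls.tangents for ls in lifted])
    sl_of = np.repeat(np.arange(len(lifted)), counts)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    within = np.concatenate([np.arange(c) for c in counts])
    is_source = within % subsample == 0

    out = np.zeros(len(pts))
    if len(bundle) > 1:
        pairs = cKDTree(pts).query_pairs(cutoff, output_type="ndarray")
        if len(pairs):
            a, b = pairs[:, 0], pairs[:, 1]
            keep = sl_of[a] != sl_of[b]
            a, b = a[keep], b[keep]
            for lo in range(0, len(a), _PAIR_CHUNK):
                sl = slice(lo, lo + _PAIR_CHUNK)
                aa, bb = a[sl], b[sl]
                dy = pts[aa] - pts[bb]
                if table is not None:
                    vals = lookup(table, dy, tans[aa], tans[bb])
                else:
                    vals = eval_kernel_fast(dy, tans[aa], tans[bb], params)
                # kernel is symmetric under pose inversion and antipodal flips,
                # so one evaluation serves both directions of the pair
                np.add.at(out, bb[is_source[aa]], vals[is_source[aa]])
                np.add.at(out, aa[is_source[bb]], vals[is_source[bb]])
    values = [out[offsets[i] : offsets[i + 1]] for i in range(len(lifted))]
    return FBCProfile(indices=bundle.indices.copy(), values=values)


def afbc_window(profile: np.ndarray, alpha: float = DEFAULT_ALPHA, step: float = DEFAULT_STEP) -> float:
    """Minimum mean FBC over sliding windows of physical length ``alpha``.

    The window spans round(alpha/step) consecutive points; a profile shorter
    than one window falls back to its overall mean.
    """
    if alpha <= 0 or step <= 0:
        raise ValueError("alpha and step must be positive")
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise ValueError("empty FBC profile")
    wp = max(1, round(alpha / step))
    if profile.size <= wp:
        return float(profile.mean())
    cum = np.concatenate([[0.0], np.cumsum(profile)])
    means = (cum[wp:] - cum[:-wp]) / wp
    return float(means.min())


def window_points(alpha: float = DEFAULT_ALPHA, step: float = DEFAULT_STEP) -> int:
    """Number of points spanned by a window of length alpha at the given step."""
    if alpha <= 0 or step <= 0:
        raise ValueError("alpha and step must be positive")
    return max(1, round(alpha / step))


def afbc_bundle(profiles: FBCProfile) -> float:
    """Bundle-wide average FBC, pooled over all points of all streamlines."""
    allvals = np.concatenate([np.asarray(v, dtype=float) for v in profiles.values])
    if allvals.size == 0 or np.all(allvals == 0):
        raise ValueError("RFBC undefined: bundle has no coherence mass (degenerate input)")
    return float(allvals.mean())


def rfbc(
    bundle: Bundle,
    kernel: KernelParams | KernelTable,
    alpha: float = DEFAULT_ALPHA,
    step: float = DEFAULT_STEP,
    *,
    cutoff: float = DEFAULT_CUTOFF,
    subsample: int = 1,
    resample_step: float | None = None,
) -> RFBCScores:
    """Score every streamline: RFBC_i = AFBC^alpha_i / AFBC(Gamma).

    ``step`` is the point spacing of the (lifted) streamlines, which fixes
    the window size in points; pass ``resample_step`` to resample inputs that
    are not already at that spacing.  Multiplying the kernel by any positive
    constant leaves the scores unchanged.
    """
    profiles = compute_fbc(bundle, kernel, cutoff, step=resample_step, subsample=subsample)
    bundle_mean = afbc_bundle(profiles)
    af = np.array([afbc_window(v, alpha, step) for v in profiles.values])
    return RFBCScores(
        alpha=alpha,
        window_points=window_points(alpha, step),
        indices=profiles.indices,
        afbc_alpha=af,
        rfbc=af / bundle_mean,
        bundle_afbc=bundle_mean,
    )


def threshold(bundle: Bundle, scores: RFBCScores, epsilon: float) -> Bundle:
    """Retain exactly the streamlines with RFBC >= epsilon.

    Scores are not recomputed on the filtered bundle (single-pass
    convention); any epsilon above the largest score empties the bundle.
    """
    if len(scores.indices) != len(bundle) or np.any(scores.indices != bundle.indices):
        raise ValueError("scores were not computed on this bundle")
    return bundle.subset(scores.rfbc >= epsilon)
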