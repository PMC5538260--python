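"""Test-retest threshold selection and surgical damage arithmetic.

The clinically relevant quantity is the distance from a temporal-pole
landmark to the reconstructed optic radiation (ML-TP distance).  Spurious
streamlines anterior to the true Meyer's loop tip shorten it erratically, so
the coherence threshold epsilon is chosen by a test-retest sweep: score and
filter repeated tractograms over a grid of thresholds and pick the first
epsilon past which the across-repetition variability of the ML-TP distance
settles below a surgical-accuracy bound (2 mm by default).

Damage arithmetic compares a resection against the pre-/post-operative
ML-TP distances: predicted damage = resection length minus pre-op ML-TP,
observed damage = post-op minus pre-op ML-TP (both floored at zero), and the
margin of error bounds their discrepancy given the measurement variability.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .fbc_core import DEFAULT_ALPHA, DEFAULT_CUTOFF, DEFAULT_STEP, rfbc
from .tract_model import Bundle

__all__ = [
    "Landmark",
    "SweepResult",
    "DamageReport",
    "ml_tp_distance",
    "sweep",
    "select_epsilon",
    "predict_damage",
    "observed_damage",
    "margin_of_error",
    "DEFAULT_SIGMA_MAX",
    "DEFAULT_GRID_STEP",
]

DEFAULT_SIGMA_MAX = 2.0    # mm; maximal acceptable test-retest variability
DEFAULT_GRID_STEP = 0.005  # epsilon grid resolution
DEFAULT_N_REALIZATIONS = 10


@dataclasses.dataclass(frozen=True)
class Landmark:
    """One or more landmark coordinates in world-space mm (temporal pole)."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
            raise ValueError("landmark must be a nonempty (K, 3) coordinate set")
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmark coordinates must be finite")
        object.__setattr__(self, "points", pts)

    @classmethod
    def from_text(cls, path) -> "Landmark":
        """Load whitespace-separated 'x y z' mm lines."""
        return cls(np.loadtxt(path, ndmin=2))


@dataclasses.dataclass(frozen=True)
class SweepResult:
    """Epsilon sweep outcome: per-threshold ML-TP statistics across repetitions."""

    epsilon_grid: np.ndarray         # strictly increasing, starts at 0
    distances: np.ndarray            # (n_eps, n_realizations), NaN where bundle emptied
    mu: np.ndarray                   # mean ML-TP per epsilon (over available repetitions)
    sigma: np.ndarray                # sample sd (ddof=1) per epsilon
    epsilon_max: float               # first threshold emptying every repetition
    scores: list | None = None       # per-realization RFBCScores (for reuse)

    def n_available(self) -> np.ndarray:
        return np.sum(~np.isnan(self.distances), axis=1)


@dataclasses.dataclass(frozen=True)
class DamageReport:
    preop_mltp: float
    sigma_pre: float
    postop_mltp: float
    sigma_post: float
    resection_length: float
    predicted_damage: float
    observed_damage: float
    margin_of_error: float


def ml_tp_distance(bundle: Bundle, landmark: Landmark) -> float:
    """Closest approach (mm) between the landmark set and the bundle.

    Minimum Euclidean distance over all (landmark point, streamline point)
    pairs.  Removing streamlines can only increase it, which is what makes
    the sweep statistics monotone per repetition.
    """
    if len(bundle) == 0:
        raise ValueError("no streamlines at this epsilon")
    best = np.inf
    for s in bundle:
        d = np.linalg.norm(s.points[:, None, :] - landmark.points[None, :, :], axis=2)
        best = min(best, float(d.min()))
    return best


def _per_streamline_distance(bundle: Bundle, landmark: Landmark) -> np.ndarray:
    out = np.empty(len(bundle))
    for i, s in enumerate(bundle):
        d = np.linalg.norm(s.points[:, None, :] - landmark.points[None, :, :], axis=2)
        out[i] = d.min()
    return out


def sweep(
    realizations: list[Bundle],
    landmark: Landmark,
    kernel,
    alpha: float = DEFAULT_ALPHA,
    step: float = DEFAULT_STEP,
    epsilon_grid: np.ndarray | None = None,
    *,
    cutoff: float = DEFAULT_CUTOFF,
    grid_step: float = DEFAULT_GRID_STEP,
    resample_step: float | None = None,
) -> SweepResult:
    """Score each repetition once, then trace ML-TP statistics over epsilon.

    Each realization emulates one probabilistic-tractography run of the same
    bundle.  For every epsilon the realizations are filtered on their fixed
    scores and the ML-TP distance recomputed; mean and sample standard
    deviation (ddof=1) are taken over the repetitions whose filtered bundle
    is nonempty.  The grid is truncated at the first epsilon where every
    repetition empties, which operationalizes epsilon_max.
    """
    if len(realizations) < 2:
        raise ValueError("test-retest sweep needs at least 2 realizations")
    scores = [
        rfbc(b, kernel, alpha, step, cutoff=cutoff, resample_step=resample_step)
        for b in realizations
    ]
    dists = [_per_streamline_distance(b, landmark) for b in realizations]
    max_rfbc = max(float(s.rfbc.max()) for s in scores)
    if epsilon_grid is None:
        epsilon_grid = np.arange(0.0, max_rfbc + 2 * grid_step, grid_step)
    epsilon_grid = np.asarray(epsilon_grid, dtype=float)
    if epsilon_grid[0] != 0 or np.any(np.diff(epsilon_grid) <= 0):
        raise ValueError("epsilon grid must start at 0 and increase strictly")

    n_rep = len(realizations)
    table = np.full((len(epsilon_grid), n_rep), np.nan)
    for r in range(n_rep):
        order = np.argsort(scores[r].rfbc)
        srt_scores = scores[r].rfbc[order]
        # suffix minima of distances over streamlines with rfbc >= eps
        suffix_min = np.minimum.accumulate(dists[r][order][::-1])[::-1]
        pos = np.searchsorted(srt_scores, epsilon_grid, side="left")
        valid = pos < len(srt_scores)
        table[valid, r] = suffix_min[pos[valid]]

    nonempty = np.any(~np.isnan(table), axis=1)
    if not nonempty[0]:
        raise ValueError("no realization has streamlines at epsilon = 0")
    last = np.max(np.nonzero(nonempty)[0])
    eps_max = float(
        epsilon_grid[last + 1] if last + 1 < len(epsilon_grid) else epsilon_grid[-1] + grid_step
    )
    grid = epsilon_grid[: last + 1]
    table = table[: last + 1]
    avail = ~np.isnan(table)
    counts = avail.sum(axis=1)
    filled = np.where(avail, table, 0.0)
    mu = filled.sum(axis=1) / counts
    ss = np.where(avail, (table - mu[:, None]) ** 2, 0.0).sum(axis=1)
    sigma = np.sqrt(ss / np.maximum(counts - 1, 1))
    return SweepResult(grid, table, mu, sigma, eps_max, scores=scores)


def select_epsilon(
    sweep_result: SweepResult, sigma_max: float = DEFAULT_SIGMA_MAX
) -> tuple[float, bool]:
    """First stable threshold: the smallest epsilon > 0 whose variability is a
    (non-strict) local minimum at or below ``sigma_max``.

    Returns (epsilon_selected, fallback_flag).  If no interior local minimum
    satisfies the bound, the smallest epsilon with sigma <= sigma_max is
    returned with the flag set.  If the variability never reaches the bound,
    the stability analysis failed and an error is raised.
    """
    grid = sweep_result.epsilon_grid
    sigma = sweep_result.sigma
    if len(grid) < 3:
        raise ValueError("sweep needs at least 3 grid points")
    for i in range(1, len(grid) - 1):
        if grid[i] > 0 and sigma[i] <= sigma_max and sigma[i - 1] >= sigma[i] <= sigma[i + 1]:
            return float(grid[i]), False
    ok = np.nonzero((grid > 0) & (sigma <= sigma_max))[0]
    if len(ok) == 0:
        raise ValueError(f"no stable region: variability never drops to {sigma_max} mm")
    return float(grid[ok[0]]), True


def predict_damage(preop_mltp: float, resection_length: float) -> float:
    """Predicted resection damage to the bundle: resection reach beyond the
    pre-operative ML-TP distance, floored at zero."""
    if preop_mltp < 0 or resection_length < 0:
        raise ValueError("distances must be nonnegative")
    return max(0.0, resection_length - preop_mltp)


def observed_damage(preop_mltp: float, postop_mltp: float) -> float:
    """Observed damage: post-operative recession of the ML-TP distance, floored at zero."""
    if preop_mltp < 0 or postop_mltp < 0:
        raise ValueError("distances must be nonnegative")
    return max(0.0, postop_mltp - preop_mltp)


def margin_of_error(
    predicted: float, sigma_pred: float, observed: float, sigma_obs: float
) -> float:
    """Maximal discrepancy between observed and predicted damage consistent
    with both uncertainty intervals: (observed + sigma_obs) - (predicted - sigma_pred).

    Convention: sigma_pred is the pre-operative ML-TP variability and
    sigma_obs the summed pre- and post-operative variabilities.
    """
    if sigma_pred < 0 or sigma_obs < 0:
        raise ValueError("sigmas must be nonnegative")
    return (observed + sigma_obs) - (predicted - sigma_pred)


def damage_report(
    preop_mltp: float,
    sigma_pre: float,
    postop_mltp: float,
    sigma_post: float,
    resection_length: float,
) -> DamageReport:
    """Full damage arithmetic from measured distances and resection length."""
    pred = predict_damage(preop_mltp, resection_length)
    obs = observed_damage(preop_mltp, postop_mltp)
    moe = margin_of_error(pred, sigma_pre, obs, sigma_pre + sigma_post)
    return DamageReport(
        preop_mltp=preop_mltp,
        sigma_pre=sigma_pre,
        postop_mltp=postop_mltp,
        sigma_post=sigma_post,
        resection_length=resection_length,
        predicted_damage=pred,
        observed_damage=obs,
        margin_of_error=moe,
    )
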