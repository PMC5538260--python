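"""Seeded synthetic streamline bundles with planted spurious outliers.

The generator emulates the statistical situation of optic-radiation
tractometry without any scan: a coherent C-shaped bundle (a Meyer's-loop-like
sweep) whose streamlines are transverse-jittered copies of a circular-arc
centerline, plus planted poorly-aligned streamlines that overshoot the
anterior tip of the bundle toward the temporal-pole landmark, and repeated
stochastic realizations of the whole construction standing in for repeated
probabilistic tractography runs.

Geometry defaults put the clean landmark-to-bundle distance near 30 mm, the
scale reported for the Meyer's loop to temporal pole distance in adults, so
that millimetre tolerances in the stability analysis are meaningful.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .stability import Landmark
from .tract_model import Bundle, Streamline, resample

__all__ = ["BundleSpec", "SpuriousSpec", "make_bundle", "add_spurious", "make_realizations"]


@dataclasses.dataclass(frozen=True)
class BundleSpec:
    """Parameters of the clean synthetic bundle.

    The centerline is a planar circular arc of the given radius and arc
    length; each streamline is the centerline translated by an isotropic
    3D normal offset (transverse jitter) and resampled at ``step``.
    """

    n_streamlines: int = 30
    jitter_sd: float = 1.0      # mm
    step: float = 0.2           # mm
    radius: float = 15.0        # mm
    arc_length: float = 60.0    # mm
    landmark_distance: float = 32.0  # mm beyond the anterior tip
    seed: int = 0

    def __post_init__(self):
        if self.n_streamlines < 1:
            raise ValueError("n_streamlines must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.step <= 0 or self.radius <= 0 or self.arc_length <= 0:
            raise ValueError("step, radius and arc_length must be positive")

    def centerline(self) -> np.ndarray:
        """Arc points at exactly ``step`` arc-length spacing (endpoint kept)."""
        span = self.arc_length / self.radius
        n = int(np.floor(self.arc_length / self.step))
        thetas = -span + np.arange(n + 1) * (self.step / self.radius)
        if span - n * (self.step / self.radius) > 1e-9 / self.radius:
            thetas = np.append(thetas, 0.0)
        return np.column_stack(
            [self.radius * np.cos(thetas), self.radius * np.sin(thetas), np.zeros_like(thetas)]
        )

    def tip(self) -> np.ndarray:
        """Anterior end of the centerline."""
        return np.array([self.radius, 0.0, 0.0])

    def anterior_direction(self) -> np.ndarray:
        """Unit direction from the bundle toward the landmark (radial at the
        tip, so the tip is the unique anterior extreme of the C-arc)."""
        return np.array([1.0, 0.0, 0.0])

    def landmark(self) -> Landmark:
        """Temporal-pole stand-in on the tip axis, ``landmark_distance`` out."""
        return Landmark(self.tip() + self.landmark_distance * self.anterior_direction())


@dataclasses.dataclass(frozen=True)
class SpuriousSpec:
    """Parameters of planted spurious streamlines.

    Each planted streamline departs from a bundle point at roughly the given
    angular deviation from the local tangent and runs straight to a point
    ``anterior_offset`` mm beyond the most anterior bundle point, emulating
    tracking artifacts that overshoot the Meyer's loop tip.
    """

    n_spurious: int = 3
    anterior_offset: float = 10.0   # mm beyond the bundle's anterior extent
    angular_deviation: float = 45.0  # degrees from the local bundle tangent
    ring_radius: float = 4.0        # mm; overshoot endpoints scatter on this ring
    seed: int = 0

    def __post_init__(self):
        if self.n_spurious < 0:
            raise ValueError("n_spurious must be >= 0")


def make_bundle(spec: BundleSpec) -> Bundle:
    """Generate the clean bundle; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    center = spec.centerline()
    streamlines = []
    for _ in range(spec.n_streamlines):
        offset = rng.normal(0.0, spec.jitter_sd, size=3) if spec.jitter_sd > 0 else np.zeros(3)
        streamlines.append(resample(Streamline(center + offset), spec.step))
    labels = np.full(spec.n_streamlines, "clean")
    return Bundle(streamlines, labels=labels)


def add_spurious(bundle: Bundle, spec: SpuriousSpec, geometry: BundleSpec) -> Bundle:
    """Append planted spurious streamlines with ground-truth labels.

    ``geometry`` supplies the anterior axis of the bundle the spurious
    streamlines overshoot.  The endpoint of each planted streamline lies
    ``anterior_offset`` mm beyond the most anterior point of the input bundle,
    scattered around the tip axis on a ring of ``ring_radius``; with the
    default radius the overshooting tips are mutually farther apart than the
    density cutoff, so planted streamlines cannot lend each other coherence
    there, and the landmark-to-bundle distance shrinks by nearly the full
    offset.
    """
    if spec.n_spurious == 0:
        return bundle
    rng = np.random.default_rng(spec.seed)
    tip = geometry.tip()
    a_dir = geometry.anterior_direction()
    # orthonormal frame transverse to the anterior axis
    u = np.cross(a_dir, [0.0, 0.0, 1.0])
    if np.linalg.norm(u) < 1e-6:
        u = np.cross(a_dir, [1.0, 0.0, 0.0])
    u /= np.linalg.norm(u)
    w = np.cross(a_dir, u)
    all_pts = np.concatenate([s.points for s in bundle])
    a_max = float(np.max((all_pts - tip) @ a_dir))
    target_dev = np.deg2rad(spec.angular_deviation)
    base_azimuth = rng.uniform(0.0, 2.0 * np.pi)

    new_streamlines = [s.points for s in bundle]
    for j in range(spec.n_spurious):
        psi = base_azimuth + 2.0 * np.pi * j / spec.n_spurious + rng.normal(0.0, 0.05)
        lat = spec.ring_radius * (np.cos(psi) * u + np.sin(psi) * w)
        endpoint = tip + (a_max + spec.anterior_offset) * a_dir + lat

        donor = bundle.streamlines[rng.integers(len(bundle))]
        pts = donor.points
        tan = np.gradient(pts, axis=0)
        tan /= np.linalg.norm(tan, axis=1, keepdims=True)
        # candidate departures: anterior half of the donor streamline
        anterior = (pts - tip) @ a_dir
        half = anterior >= np.median(anterior)
        cand = np.nonzero(half)[0]
        to_end = endpoint - pts[cand]
        to_end /= np.linalg.norm(to_end, axis=1, keepdims=True)
        dev = np.arccos(np.clip(np.abs(np.sum(to_end * tan[cand], axis=1)), 0.0, 1.0))
        k = cand[np.argmin(np.abs(dev - target_dev))]
        planted = resample(Streamline(np.vstack([pts[k], endpoint])), geometry.step)
        new_streamlines.append(planted.points)

    labels = np.concatenate(
        [
            bundle.labels if bundle.labels is not None else np.full(len(bundle), "clean"),
            np.full(spec.n_spurious, "spurious"),
        ]
    )
    return Bundle(new_streamlines, labels=labels, realization=bundle.realization)


def make_realizations(
    spec: BundleSpec,
    spurious: SpuriousSpec,
    n_rep: int = 10,
    master_seed: int = 0,
    plant_probability: float = 0.5,
) -> list[Bundle]:
    """Independent labeled realizations emulating repeated tractography runs.

    Per-realization seeds derive from ``numpy.random.SeedSequence(master_seed)``
    spawned in order (a stable scheme across releases); spurious streamlines
    are planted independently per realization with ``plant_probability``.
    """
    if n_rep < 2:
        raise ValueError("need at least 2 realizations")
    children = np.random.SeedSequence(master_seed).spawn(n_rep)
    out = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        b_seed = int(rng.integers(2**31))
        s_seed = int(rng.integers(2**31))
        bundle = make_bundle(dataclasses.replace(spec, seed=b_seed))
        bundle.realization = r
        if spurious.n_spurious > 0 and rng.random() < plant_probability:
            bundle = add_spurious(bundle, dataclasses.replace(spurious, seed=s_seed), spec)
        out.append(bundle)
    return out
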