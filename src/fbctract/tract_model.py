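"""Streamline data model, tractogram I/O, resampling, and lifting.

A streamline is an ordered polyline in world-space millimetres; a bundle is an
indexed collection of streamlines.  Before density estimation each streamline
is *lifted* to position-orientation space R^3 x S^2 by attaching the local
unit tangent to every point.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import nibabel as nib
from nibabel.streamlines import Tractogram
from nibabel.streamlines.tck import TckFile
from nibabel.streamlines.trk import TrkFile

__all__ = [
    "Streamline",
    "LiftedStreamline",
    "Bundle",
    "read_tractogram",
    "write_tractogram",
    "resample",
    "filter_by_length",
    "lift",
    "arc_length",
]


def _validate_points(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("streamline points must be an (N, 3) array")
    if len(points) < 2:
        raise ValueError("a streamline needs at least 2 points")
    if not np.all(np.isfinite(points)):
        raise ValueError("streamline coordinates must be finite")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(seg <= 0):
        raise ValueError("consecutive streamline points must be distinct")
    return points


@dataclasses.dataclass(frozen=True)
class Streamline:
    """Ordered 3D polyline in world-space millimetres."""

    points: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "points", _validate_points(self.points))

    def __len__(self) -> int:
        return len(self.points)

    @property
    def length(self) -> float:
        return arc_length(self.points)

    def reversed(self) -> "Streamline":
        return Streamline(self.points[::-1].copy())


@dataclasses.dataclass(frozen=True)
class LiftedStreamline:
    """Streamline points paired with unit tangents: elements (y_k, n_k) in R^3 x S^2."""

    points: np.ndarray
    tangents: np.ndarray

    def __post_init__(self):
        if self.points.shape != self.tangents.shape:
            raise ValueError("points and tangents must have matching shapes")
        norms = np.linalg.norm(self.tangents, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("tangents must be unit vectors")

    def __len__(self) -> int:
        return len(self.points)


class Bundle:
    """Indexed collection of streamlines.

    Filtering returns sub-collections that keep the original indices, so
    per-streamline scores and ground-truth labels stay joinable across
    filtering steps.
    """

    def __init__(
        self,
        streamlines: Sequence[Streamline] | Sequence[np.ndarray],
        indices: Sequence[int] | None = None,
        labels: Sequence[str] | None = None,
        realization: int | None = None,
    ):
        self.streamlines = [
            s if isinstance(s, Streamline) else Streamline(np.asarray(s)) for s in streamlines
        ]
        if indices is None:
            indices = np.arange(len(self.streamlines))
        self.indices = np.asarray(indices, dtype=int)
        if len(self.indices) != len(self.streamlines):
            raise ValueError("indices must match streamline count")
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("streamline indices must be unique")
        self.labels = None if labels is None else np.asarray(labels)
        if self.labels is not None and len(self.labels) != len(self.streamlines):
            raise ValueError("labels must match streamline count")
        self.realization = realization

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def subset(self, mask: np.ndarray) -> "Bundle":
        mask = np.asarray(mask, dtype=bool)
        return Bundle(
            [s for s, m in zip(self.streamlines, mask) if m],
            indices=self.indices[mask],
            labels=None if self.labels is None else self.labels[mask],
            realization=self.realization,
        )

    def map_streamlines(self, fn) -> "Bundle":
        return Bundle(
            [fn(s) for s in self.streamlines],
            indices=self.indices.copy(),
            labels=None if self.labels is None else self.labels.copy(),
            realization=self.realization,
        )


def arc_length(points: np.ndarray) -> float:
    """Polyline arc length in mm."""
    return float(np.sum(np.linalg.norm(np.diff(np.asarray(points, dtype=float), axis=0), axis=1)))


# ---------------------------------------------------------------------------
# tractogram I/O


def _format_for(path, format: str | None) -> str:
    if format is None:
        format = Path(path).suffix.lstrip(".").lower()
    format = format.lower()
    if format not in ("tck", "trk"):
        raise ValueError(f"unknown tractogram format {format!r}; expected 'tck' or 'trk'")
    return format


def read_tractogram(path, format: str | None = None) -> Bundle:
    """Read a TCK or TRK tractogram into a Bundle in world-space mm.

    TRK coordinates are mapped from voxel space to world space using the
    header affine; a TRK file without a usable affine is an error rather than
    a silent voxel-space passthrough.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    format = _format_for(path, format)
    cls = TckFile if format == "tck" else TrkFile
    if not cls.is_correct_format(str(path)):
        raise ValueError(f"{path} is not a valid {format.upper()} file")
    if format == "trk":
        # nibabel silently assumes identity when the header's vox_to_ras was
        # never recorded (all zeros); inspect the raw field instead
        raw = path.read_bytes()[:1000]
        hdr_size = np.frombuffer(raw[996:1000], dtype="<i4")[0]
        order = "<" if hdr_size == 1000 else ">"
        affine = np.frombuffer(raw[440:504], dtype=f"{order}f4").reshape(4, 4)
        if not np.all(np.isfinite(affine)) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError(f"{path} has no usable voxel-to-world affine")
    tf = cls.load(str(path))
    # nibabel yields streamlines in RAS+ mm for both formats
    return Bundle([np.asarray(s, dtype=float) for s in tf.streamlines])


def write_tractogram(bundle: Bundle, path, format: str | None = None) -> None:
    """Write a bundle to TCK or TRK; coordinates are world-space mm."""
    path = Path(path)
    format = _format_for(path, format)
    tg = Tractogram([s.points for s in bundle], affine_to_rasmm=np.eye(4))
    if format == "tck":
        TckFile(tg).save(str(path))
        return
    # TRK needs a voxel grid; use a unit-voxel identity grid covering the data
    if len(bundle):
        upper = np.max([s.points.max(axis=0) for s in bundle], axis=0)
        dims = np.maximum(np.ceil(np.abs(upper)).astype(int) + 1, 1)
    else:
        dims = np.ones(3, dtype=int)
    header = {
        "voxel_to_rasmm": np.eye(4, dtype=np.float32),
        "voxel_sizes": np.ones(3, dtype=np.float32),
        "dimensions": dims.astype(np.int16),
        "voxel_order": "RAS",
    }
    TrkFile(tg, header=header).save(str(path))


# ---------------------------------------------------------------------------
# resampling, filtering, lifting


def resample(s: Streamline, step: float) -> Streamline:
    """Resample so consecutive points are exactly ``step`` mm apart.

    Marches along the polyline placing each point at Euclidean distance
    ``step`` from the previous one (the spacing convention of streamline
    tracking itself): the output polyline is equally spaced by its own arc
    length, and the operation is exactly idempotent.  The endpoint is kept
    even when the final interval is shorter.  If ``step`` is at least the
    total length, the two endpoints are returned.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    pts = s.points
    if step >= s.length:
        return Streamline(np.vstack([pts[0], pts[-1]]))
    out = [pts[0]]
    cur = pts[0]
    j = 0  # current segment index; cur lies on segment (pts[j], pts[j+1])
    entry = pts[0]
    while True:
        hit = None
        for k in range(j, len(pts) - 1):
            a = entry if k == j else pts[k]
            d = pts[k + 1] - a
            f = a - cur
            aa = d @ d
            if aa <= 0:
                continue
            bb = 2.0 * (f @ d)
            cc = f @ f - step * step
            disc = bb * bb - 4 * aa * cc
            if disc < 0:
                continue
            t = (-bb + np.sqrt(disc)) / (2 * aa)  # forward crossing
            if 0 < t <= 1 + 1e-12:
                hit = (k, a + min(t, 1.0) * d)
                break
        if hit is None:
            if np.linalg.norm(pts[-1] - cur) > 1e-12:
                out.append(pts[-1])
            break
        j, cur = hit
        entry = cur
        out.append(cur)
    return Streamline(np.asarray(out))


def filter_by_length(bundle: Bundle, max_length: float = 114.0) -> Bundle:
    """Keep streamlines with arc length <= max_length (boundary inclusive).

    The default reproduces the anatomically motivated 114 mm upper bound on
    optic-radiation streamline length.
    """
    if max_length <= 0:
        raise ValueError("max_length must be positive")
    mask = np.array([s.length <= max_length + 1e-9 for s in bundle])
    return bundle.subset(mask)


def lift(s: Streamline) -> LiftedStreamline:
    """Attach unit tangents: central differences inside, one-sided at the ends."""
    pts = s.points
    tan = np.empty_like(pts)
    tan[0] = pts[1] - pts[0]
    tan[-1] = pts[-1] - pts[-2]
    if len(pts) > 2:
        tan[1:-1] = pts[2:] - pts[:-2]
    norms = np.linalg.norm(tan, axis=1, keepdims=True)
    if np.any(norms <= 0):
        raise ValueError("degenerate tangent (duplicate points)")
    return LiftedStreamline(pts.copy(), tan / norms)
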