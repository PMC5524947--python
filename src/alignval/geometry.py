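"""Projection-sphere geometry.

Every particle orientation in single particle analysis is a point on the unit
sphere of viewing directions (the *projection sphere*) plus an in-plane
rotation.  This module provides the geometric primitives the validation
statistics are built on: Euler-angle <-> direction conversion, point-group
symmetry, the symmetry-aware geodesic (great-circle) distance, near-uniform
angular grids restricted to one asymmetric unit, and uniform random
directions within it.

Conventions
-----------
* Euler angles are ZYZ ``(rot, tilt, psi)`` in degrees, the dominant dialect
  of deposited particle metadata.  ``tilt`` in ``[0, 180]``.
* The viewing direction depends only on ``(rot, tilt)``:
  ``d = (sin t cos r, sin t sin r, cos t)``.
* The canonical asymmetric-unit representative of a direction is its symmetry
  image with lexicographically largest ``(z, x, y)`` tuple.  Membership tests
  and uniform sampling both use this canonicalization, so they agree by
  construction.
* Antipodal directions ``p`` and ``-p`` are distinct (no mirror
  identification), matching full-sphere angular searches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Orientation",
    "SymmetryGroup",
    "ProjectionGrid",
    "euler_to_direction",
    "direction_to_euler",
    "geodesic_distance",
    "geodesic_distance_matrix",
    "sample_projection_grid",
    "random_directions_in_au",
]


@dataclass(frozen=True)
class Orientation:
    """Full per-particle alignment: ZYZ Euler triplet (degrees) + 2D shift (pixels)."""

    rot: float = 0.0
    tilt: float = 0.0
    psi: float = 0.0
    shift_x: float = 0.0
    shift_y: float = 0.0

    def direction(self) -> np.ndarray:
        return euler_to_direction(self.rot, self.tilt)


def euler_to_direction(rot: float | np.ndarray, tilt: float | np.ndarray) -> np.ndarray:
    """Viewing direction(s) for ZYZ Euler angles ``rot``, ``tilt`` in degrees.

    Returns a unit 3-vector ``(sin t cos r, sin t sin r, cos t)``; broadcasts,
    producing an ``(..., 3)`` array for array input.
    """
    r = np.deg2rad(rot)
    t = np.deg2rad(tilt)
    return np.stack(
        np.broadcast_arrays(np.sin(t) * np.cos(r), np.sin(t) * np.sin(r), np.cos(t)),
        axis=-1,
    )


def direction_to_euler(d: np.ndarray) -> tuple[float, float]:
    """Inverse of :func:`euler_to_direction`: ``(rot, tilt)`` in degrees.

    ``rot`` is returned in ``[-180, 180)``; at the poles (tilt 0 or 180) rot is
    degenerate and reported as 0.
    """
    d = np.asarray(d, dtype=float)
    tilt = np.degrees(np.arccos(np.clip(d[..., 2], -1.0, 1.0)))
    rot = np.degrees(np.arctan2(d[..., 1], d[..., 0]))
    rot = np.where(np.sin(np.deg2rad(tilt)) < 1e-12, 0.0, rot)
    rot = ((rot + 180.0) % 360.0) - 180.0
    return float(rot) if rot.ndim == 0 else rot, float(tilt) if np.ndim(tilt) == 0 else tilt


class SymmetryGroup:
    """Point group (C*n*, D*n*, T, O, I) as an explicit list of rotation matrices.

    The group defines the asymmetric unit over which orientations are sampled;
    C1 is the whole sphere.
    """

    def __init__(self, label: str):
        label = label.strip().upper()
        try:
            rots = Rotation.create_group(label)
        except ValueError as exc:
            raise ValueError(f"unknown point-group label {label!r}") from exc
        self.label = label
        self.matrices = rots.as_matrix()  # (|G|, 3, 3), contains identity

    @property
    def order(self) -> int:
        return len(self.matrices)

    def orbit(self, d: np.ndarray) -> np.ndarray:
        """All symmetry images of direction(s) ``d``: shape ``(..., |G|, 3)``."""
        d = np.asarray(d, dtype=float)
        return np.einsum("gij,...j->...gi", self.matrices, d)

    def canonicalize(self, d: np.ndarray) -> np.ndarray:
        """Canonical asymmetric-unit representative: the symmetry image with
        lexicographically largest ``(z, x, y)``."""
        orb = self.orbit(d)  # (..., |G|, 3)
        key = np.stack([orb[..., 2], orb[..., 0], orb[..., 1]], axis=-1)
        # lexicographic argmax over the group axis
        idx = _lex_argmax(key)
        return np.take_along_axis(orb, idx[..., None, None], axis=-2).squeeze(-2)

    def in_asymmetric_unit(self, d: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        """True where ``d`` equals its own canonical representative."""
        return np.all(np.abs(self.canonicalize(d) - d) <= atol, axis=-1)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SymmetryGroup({self.label!r}, order={self.order})"


def _lex_argmax(key: np.ndarray) -> np.ndarray:
    """Argmax over axis -2 by lexicographic order of the last-axis tuples."""
    # quantize-free lexicographic comparison via successive masking
    k0, k1, k2 = key[..., 0], key[..., 1], key[..., 2]
    big = np.max(np.abs(key)) * 4 + 1
    score = (k0 * big + k1) * big + k2
    return np.argmax(score, axis=-1)


@dataclass
class ProjectionGrid:
    """Near-uniform covering of one asymmetric unit at angular sampling Δ (degrees)."""

    directions: np.ndarray  # (G, 3)
    delta: float
    sym_label: str = "C1"
    eulers: np.ndarray = field(default=None, repr=False)  # (G, 2) rot, tilt degrees

    def __post_init__(self):
        if self.eulers is None:
            d = self.directions
            tilt = np.degrees(np.arccos(np.clip(d[:, 2], -1, 1)))
            rot = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
            self.eulers = np.column_stack([rot, tilt])

    def __len__(self) -> int:
        return len(self.directions)


def geodesic_distance(p: np.ndarray, q: np.ndarray, sym: SymmetryGroup | None = None) -> np.ndarray:
    """Great-circle angle between directions, minimized over symmetry operators.

    ``min_R arccos(clip(p . R q))`` in radians; a pseudo-metric on the sphere
    modulo the group.  Broadcasts over leading axes of ``p`` and ``q``.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if sym is None or sym.order == 1:
        dots = np.einsum("...i,...i->...", p, q)
        return np.arccos(np.clip(dots, -1.0, 1.0))
    qg = np.einsum("gij,...j->...gi", sym.matrices, q)  # (..., |G|, 3)
    dots = np.einsum("...i,...gi->...g", p, qg)
    return np.min(np.arccos(np.clip(dots, -1.0, 1.0)), axis=-1)


def geodesic_distance_matrix(dirs: np.ndarray, sym: SymmetryGroup | None = None) -> np.ndarray:
    """All-pairs symmetry-aware geodesic distances, shape ``(n, n)``."""
    dirs = np.asarray(dirs, dtype=float)
    if sym is None or sym.order == 1:
        dots = dirs @ dirs.T
        return np.arccos(np.clip(dots, -1.0, 1.0))
    qg = np.einsum("gij,nj->ngi", sym.matrices, dirs)  # (n, |G|, 3)
    dots = np.einsum("mi,ngi->mng", dirs, qg)
    return np.min(np.arccos(np.clip(dots, -1.0, 1.0)), axis=-1)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Equal-area spiral (Fibonacci) lattice of n points on the unit sphere."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def sample_projection_grid(delta: float, sym: SymmetryGroup | None = None) -> ProjectionGrid:
    """Angular grid at sampling rate ``delta`` degrees inside one asymmetric unit.

    An equal-area spiral lattice of the full sphere is filtered to the canonical
    asymmetric unit and de-duplicated under the symmetry-aware distance.  The
    point count is chosen so neighbouring nodes sit about ``delta`` apart
    (hexagonal-packing estimate), which keeps every point of the asymmetric
    unit within ``1.5 * delta`` of a node.
    """
    if not 0 < delta <= 30:
        raise ValueError(f"delta must be in (0, 30] degrees, got {delta}")
    if sym is None:
        sym = SymmetryGroup("C1")
    drad = np.deg2rad(delta)
    n_full = max(16, int(np.ceil(4 * np.pi * (2 / np.sqrt(3)) / drad**2)))
    pts = _fibonacci_sphere(n_full)
    pts = pts[sym.in_asymmetric_unit(pts, atol=1e-12)]
    if sym.order > 1:  # drop symmetry-near duplicates (AU boundary artefacts)
        keep: list[int] = []
        for i in range(len(pts)):
            if not keep:
                keep.append(i)
                continue
            d = geodesic_distance(pts[keep], pts[i], sym)
            if np.min(d) >= drad / 4:
                keep.append(i)
        pts = pts[keep]
    return ProjectionGrid(directions=pts, delta=delta, sym_label=sym.label)


def random_directions_in_au(
    n: int, sym: SymmetryGroup | None = None, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """``n`` i.i.d. area-uniform directions inside one asymmetric unit.

    Uniform points on the full sphere are mapped to their canonical
    representatives; the canonical map is a piecewise rotation, so area
    uniformity within the asymmetric unit is preserved.  Deterministic for a
    fixed integer seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    if sym is None or sym.order == 1:
        return v
    return sym.canonicalize(v)
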