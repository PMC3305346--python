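"""Frame-to-frame boundary point correspondence.

With every frame described by the same number N of equidistant points,
the order-preserving 1:1 mappings between two frames are exactly the N
cyclic index shifts.  The shift minimising the total squared displacement
of the points defines the correspondence; composing shifts across a movie
gives every material point a single global index, so any per-point
measure can be laid out as a kymograph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boundary import BoundaryMovie


def _signed_shift(s: int, n: int) -> int:
    """Map a shift to its cyclically signed representative in [-n/2, n/2)."""
    return int((s + n // 2) % n - n // 2)


def match_boundaries(a: np.ndarray, b: np.ndarray) -> tuple[int, float]:
    """Best cyclic shift aligning boundary ``b`` to boundary ``a``.

    Returns ``(offset, cost)`` where ``offset`` is the shift ``s``
    minimising ``sum_i ||a[i] - b[(i + s) % N]||**2`` and ``cost`` is that
    minimum (µm²).  Ties (possible on symmetric shapes) are broken toward
    the smaller cyclically-signed ``|s|``, then toward negative ``s``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError(f"boundary shape mismatch: {a.shape} vs {b.shape}")
    n = len(a)
    sa = float(np.sum(a * a))
    sb = float(np.sum(b * b))
    # cost(s) = sa + sb - 2 * sum_i a[i].b[(i+s) % N]
    dots = np.array([float(np.sum(a * np.roll(b, -s, axis=0))) for s in range(n)])
    costs = sa + sb - 2.0 * dots
    cmin = costs.min()
    # tolerance keeps tie-breaking deterministic under float round-off
    ties = np.flatnonzero(costs <= cmin + 1e-9 * max(1.0, abs(cmin)))
    signed = np.array([_signed_shift(s, n) for s in ties])
    order = np.lexsort((signed, np.abs(signed)))  # smallest |s|, then negative s
    best = ties[order[0]]
    return _signed_shift(int(best), n), float(costs[best])


@dataclass
class TrackedBoundarySeries:
    """A boundary movie with point identity aligned across frames.

    ``points[t, k]`` is the same material point for every ``t``;
    ``offsets[t]`` is the cumulative cyclic shift (in [0, N)) that was
    applied to frame ``t``'s original point numbering.
    """

    points: np.ndarray          # (T, N, 2), µm, aligned
    offsets: np.ndarray         # (T,), ints in [0, N)
    frame_interval: float       # s
    match_costs: np.ndarray = None  # (T-1,) µm², pairwise minima

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=int)
        if self.match_costs is None:
            self.match_costs = np.zeros(self.n_frames - 1)

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def n_points(self) -> int:
        return self.points.shape[1]

    def spacings(self) -> np.ndarray:
        seg = np.linalg.norm(np.roll(self.points, -1, axis=1) - self.points, axis=2)
        return seg.sum(axis=1) / self.n_points

    def centroids(self) -> np.ndarray:
        from .boundary import polygon_centroid
        return np.array([polygon_centroid(p) for p in self.points])


def track_series(movie: BoundaryMovie | np.ndarray,
                 frame_interval: float | None = None) -> TrackedBoundarySeries:
    """Track all boundary points of a movie simultaneously.

    Applies :func:`match_boundaries` to each successive frame pair and
    composes the offsets so one global index follows the same material
    point through the whole movie.
    """
    if isinstance(movie, BoundaryMovie):
        pts = movie.points
        dt = movie.frame_interval
        if movie.border_flags is not None and movie.border_flags.any():
            bad = np.flatnonzero(movie.border_flags).tolist()
            raise ValueError(f"frames touching the image border: {bad}")
    else:
        pts = np.asarray(movie, dtype=float)
        dt = frame_interval
        if dt is None:
            raise ValueError("frame_interval required for a bare array")
    T, n = pts.shape[0], pts.shape[1]
    if T < 2:
        raise ValueError("need at least 2 frames")

    aligned = np.empty_like(pts)
    aligned[0] = pts[0]
    offsets = np.zeros(T, dtype=int)
    costs = np.empty(T - 1)
    for t in range(T - 1):
        # s is cumulative already: the previous frame passed in is aligned
        s, c = match_boundaries(aligned[t], pts[t + 1])
        offsets[t + 1] = s % n
        aligned[t + 1] = np.roll(pts[t + 1], -s, axis=0)
        costs[t] = c
    return TrackedBoundarySeries(points=aligned, offsets=offsets,
                                 frame_interval=dt, match_costs=costs)
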