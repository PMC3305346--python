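"""Closed-boundary geometry primitives.

A cell boundary is an ordered, cyclic sequence of ``(x, y)`` vertices in
micrometres.  The closing edge from the last vertex back to the first is
implicit.  All downstream analysis assumes boundaries are *simple*
(non-self-intersecting), oriented counterclockwise (positive shoelace
signed area), and, within a frame, sampled at uniform arc-length spacing.
Image coordinates map to this frame with the origin at the centre of the
top-left pixel, ``x`` increasing along columns and ``y`` along rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as _MplPath
from shapely.geometry import LinearRing


class DegenerateBoundaryError(ValueError):
    """Raised for zero-perimeter or otherwise unusable boundary input."""


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (N, 2) array of vertices, got {pts.shape}")
    return pts


def signed_area(points) -> float:
    """Shoelace signed area; positive for counterclockwise orientation."""
    pts = _as_points(points)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(points) -> float:
    """Enclosed area in µm² (absolute value of the shoelace sum)."""
    return abs(signed_area(points))


def perimeter(points) -> float:
    """Perimeter in µm, including the implicit closing edge."""
    pts = _as_points(points)
    return float(np.sum(np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)))


def polygon_centroid(points) -> np.ndarray:
    """Area centroid of the closed polygon (µm)."""
    pts = _as_points(points)
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if a == 0.0:
        raise DegenerateBoundaryError("zero-area polygon has no centroid")
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def is_counterclockwise(points) -> bool:
    return signed_area(points) > 0.0


def ensure_counterclockwise(points) -> np.ndarray:
    """Return the boundary with counterclockwise orientation.

    A clockwise input is reversed in place order but keeps its first
    vertex first, so the vertex *set* is unchanged.
    """
    pts = _as_points(points)
    if signed_area(pts) < 0.0:
        pts = np.roll(pts[::-1], 1, axis=0)
    return pts


def is_simple(points) -> bool:
    """True if the closed polygon does not self-intersect."""
    pts = _as_points(points)
    if len(pts) < 3:
        return False
    return LinearRing(pts).is_valid


def point_spacing(points) -> float:
    """Mean arc-length spacing, perimeter / N (µm)."""
    pts = _as_points(points)
    return perimeter(pts) / len(pts)


def resample_closed(points, n_points: int) -> np.ndarray:
    """Resample a closed polyline to ``n_points`` equidistant vertices.

    The first output vertex coincides with the first input vertex; spacing
    is uniform in arc length around the full (closed) perimeter.
    """
    pts = _as_points(points)
    if len(pts) < 3:
        raise DegenerateBoundaryError("need at least 3 vertices")
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0.0:
        raise DegenerateBoundaryError("zero-perimeter input")
    target = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(target, s, closed[:, 0])
    y = np.interp(target, s, closed[:, 1])
    return np.column_stack([x, y])


def resample_boundary(points, n_points: int) -> np.ndarray:
    """Normalise orientation to counterclockwise and resample equidistantly."""
    return resample_closed(ensure_counterclockwise(points), n_points)


def points_in_polygon(polygon, query) -> np.ndarray:
    """Vectorised point-in-polygon test (matplotlib Path winding test)."""
    poly = _as_points(polygon)
    q = np.atleast_2d(np.asarray(query, dtype=float))
    return _MplPath(poly, closed=True).contains_points(q)


def outward_normals(points) -> np.ndarray:
    """Unit outward normals from central-difference tangents (CCW boundary)."""
    pts = ensure_counterclockwise(points)
    tang = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    nrm = np.column_stack([tang[:, 1], -tang[:, 0]])
    lengths = np.linalg.norm(nrm, axis=1)
    lengths[lengths == 0.0] = 1.0
    return nrm / lengths[:, None]


def cyclic_index_difference(j, i, n: int) -> np.ndarray:
    """Signed shortest cyclic difference ``j - i`` mapped to [-n/2, n/2)."""
    return (np.asarray(j, dtype=float) - np.asarray(i, dtype=float) + n / 2.0) % n - n / 2.0


@dataclass
class BoundaryMovie:
    """A per-frame stack of equal-count boundaries.

    Attributes
    ----------
    points : ndarray, shape (T, N, 2)
        Boundary vertices in µm; every frame CCW with uniform spacing.
    frame_interval : float
        Time between frames, seconds.
    border_flags : ndarray of bool, shape (T,)
        True where the cell touched the image border during extraction
        (cyclic measures are unreliable there).
    """

    points: np.ndarray
    frame_interval: float
    border_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[2] != 2:
            raise ValueError("points must have shape (T, N, 2)")
        if self.points.shape[0] < 2:
            raise ValueError("a movie needs at least 2 frames")
        if not np.isfinite(self.frame_interval) or self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive and finite")
        if self.border_flags is None:
            self.border_flags = np.zeros(self.n_frames, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def n_points(self) -> int:
        return self.points.shape[1]

    def perimeters(self) -> np.ndarray:
        return np.array([perimeter(p) for p in self.points])

    def spacings(self) -> np.ndarray:
        """Per-frame mean point spacing, perimeter(t)/N (µm)."""
        return self.perimeters() / self.n_points

    def centroids(self) -> np.ndarray:
        return np.array([polygon_centroid(p) for p in self.points])
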