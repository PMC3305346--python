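"""Per-point curvature and whole-cell shape measures.

Curvature at boundary point ``i`` is defined through the circle passing
through points ``i - h``, ``i`` and ``i + h`` (cyclic, default h = 10):
its magnitude is the reciprocal of that circle's radius, and its sign is
positive when the midpoint of the two flanking points lies inside the
cell — so convex stretches (protrusions, the cell front and back) are
positive and indentations negative.  Whole-cell polarisation is measured
by the non-circularity P / (2*sqrt(pi*A)), normalised so a circle gives 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boundary import (
    BoundaryMovie,
    DegenerateBoundaryError,
    perimeter,
    point_spacing,
    points_in_polygon,
    polygon_area,
    polygon_centroid,
)
from .kymograph import ScalarKymograph, smooth_kymograph
from .tracking import TrackedBoundarySeries

DEFAULT_HALFWIDTH = 10


def curvature(points: np.ndarray, halfwidth: int = DEFAULT_HALFWIDTH) -> np.ndarray:
    """Signed circle-fit curvature at every boundary point (1/µm).

    For each point the circumradius of the triangle ``(i-h, i, i+h)``
    gives the magnitude; the sign comes from testing whether the midpoint
    of the flanking pair falls inside the boundary polygon.  Collinear
    stencils give exactly 0.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n <= 2 * halfwidth:
        raise ValueError(f"need more than {2 * halfwidth} points, got {n}")
    p1 = np.roll(pts, halfwidth, axis=0)   # i - h
    p2 = pts
    p3 = np.roll(pts, -halfwidth, axis=0)  # i + h
    a = np.linalg.norm(p2 - p3, axis=1)
    b = np.linalg.norm(p1 - p3, axis=1)
    c = np.linalg.norm(p1 - p2, axis=1)
    d21 = p2 - p1
    d31 = p3 - p1
    cross = d21[:, 0] * d31[:, 1] - d21[:, 1] * d31[:, 0]
    denom = a * b * c
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0, 2.0 * np.abs(cross) / denom, 0.0)
    mid = 0.5 * (p1 + p3)
    inside = points_in_polygon(pts, mid)
    sign = np.where(inside, 1.0, -1.0)
    return np.where(kappa == 0.0, 0.0, sign * kappa)


def curvature_kymograph(series: TrackedBoundarySeries | BoundaryMovie,
                        halfwidth: int = DEFAULT_HALFWIDTH,
                        smooth: tuple[int, int] | None = (3, 3)) -> ScalarKymograph:
    """Curvature of every tracked point in every frame as a kymograph.

    ``smooth=(points, frames)`` applies the standard 3x3 moving-average
    (pass None for raw values).
    """
    pts = series.points
    mat = np.stack([curvature(p, halfwidth) for p in pts], axis=1)
    kymo = ScalarKymograph(matrix=mat, quantity="curvature",
                           point_spacing=series.spacings(),
                           frame_interval=series.frame_interval)
    if smooth is not None:
        kymo = smooth_kymograph(kymo, *smooth)
    return kymo


def non_circularity(points: np.ndarray) -> float:
    """Perimeter over the perimeter of the equal-area circle.

    ``P / (2*sqrt(pi*A))``; equals 1 for a circle (up to polygonal
    discretisation) and grows as the shape elongates.
    """
    area = polygon_area(points)
    if area == 0.0:
        raise DegenerateBoundaryError("zero-area polygon")
    return perimeter(points) / (2.0 * np.sqrt(np.pi * area))


@dataclass
class PolarizationTrace:
    """Per-frame whole-cell polarisation measures.

    non_circularity: dimensionless, >= 1 up to discretisation;
    centroid: (T, 2) µm; centroid_speed: µm/min, NaN for the first frame.
    """

    non_circularity: np.ndarray
    centroid: np.ndarray
    centroid_speed: np.ndarray
    frame_interval: float


def centroid_speed(series: TrackedBoundarySeries | BoundaryMovie) -> np.ndarray:
    """Per-frame centroid speed in µm/min (NaN at the first frame)."""
    cents = np.array([polygon_centroid(p) for p in series.points])
    step = np.linalg.norm(np.diff(cents, axis=0), axis=1)
    speed = np.empty(len(cents))
    speed[0] = np.nan
    speed[1:] = step / series.frame_interval * 60.0
    return speed


def polarization_trace(series: TrackedBoundarySeries | BoundaryMovie) -> PolarizationTrace:
    """Non-circularity, centroid and centroid speed for a whole movie."""
    pts = series.points
    nc = np.array([non_circularity(p) for p in pts])
    cents = np.array([polygon_centroid(p) for p in pts])
    return PolarizationTrace(non_circularity=nc, centroid=cents,
                             centroid_speed=centroid_speed(series),
                             frame_interval=series.frame_interval)
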