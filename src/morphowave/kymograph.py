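"""Space-time kymograph container and smoothing.

A kymograph lays out a per-boundary-point scalar as an N x T matrix
(rows = boundary index, columns = frame); features traveling along the
boundary appear as tilted lines.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import uniform_filter1d


@dataclass
class ScalarKymograph:
    """N x T matrix of a per-point measure with physical calibration.

    matrix: values, rows = boundary index (cyclic), columns = frame;
    quantity: e.g. ``"curvature"`` (1/µm) or ``"motion"`` (µm/interval);
    point_spacing: per-frame mean arc-length spacing, perimeter(t)/N (µm);
    frame_interval: seconds between columns.
    """

    matrix: np.ndarray
    quantity: str
    point_spacing: np.ndarray
    frame_interval: float

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.point_spacing = np.atleast_1d(np.asarray(self.point_spacing, dtype=float))
        if self.matrix.ndim != 2:
            raise ValueError("kymograph matrix must be 2-D (points x frames)")
        if len(self.point_spacing) == 1:
            self.point_spacing = np.full(self.n_frames, self.point_spacing[0])
        if len(self.point_spacing) != self.n_frames:
            raise ValueError("point_spacing length must match frame count")

    @property
    def n_points(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def smooth_kymograph(kymo: ScalarKymograph,
                     points_window: int = 3,
                     frames_window: int = 3) -> ScalarKymograph:
    """Moving-average smoothing over the point and time axes.

    The point axis is cyclic; the time axis truncates at the movie ends
    (the mean is renormalised over the in-range part of the window, so no
    data is fabricated beyond the first/last frame).
    """
    for w, axis_len, name in ((points_window, kymo.n_points, "points_window"),
                              (frames_window, kymo.n_frames, "frames_window")):
        if w < 1 or w % 2 == 0:
            raise ValueError(f"{name} must be odd and positive, got {w}")
        if w >= axis_len:
            raise ValueError(f"{name}={w} must be smaller than the axis length {axis_len}")
    out = uniform_filter1d(kymo.matrix, points_window, axis=0, mode="wrap")
    sums = uniform_filter1d(out, frames_window, axis=1, mode="constant", cval=0.0)
    counts = uniform_filter1d(np.ones(kymo.n_frames), frames_window,
                              mode="constant", cval=0.0)
    out = sums / counts[None, :]
    return replace(kymo, matrix=out)
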