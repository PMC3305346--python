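"""Boundary extraction from image or mask stacks.

Two routes produce the same product — a closed, CCW, equidistantly
resampled boundary per frame:

* intensity images: a parametric active contour (snake) seeded from a
  circle around the object (or from the previous frame's boundary) locks
  onto the intensity edge;
* binary masks: marching-squares contour tracing of the 0.5 level set,
  bypassing the snake entirely.

Pixel coordinates are converted to µm with the origin at the centre of
the top-left pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import active_contour

from .boundary import (
    BoundaryMovie,
    DegenerateBoundaryError,
    ensure_counterclockwise,
    resample_boundary,
)

DEFAULT_N_POINTS = 400


class SegmentationError(RuntimeError):
    """Snake failed to converge on a frame."""

    def __init__(self, message, frame_index=None):
        super().__init__(message)
        self.frame_index = frame_index


class AmbiguousSceneError(ValueError):
    """Zero or multiple candidate objects in a frame."""


@dataclass
class FrameStack:
    """A time-lapse image stack with physical calibration.

    frames: (T, H, W) intensity (or 0/1 mask) array;
    pixel_size: µm per pixel; frame_interval: seconds per frame.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if self.frames.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        for name in ("pixel_size", "frame_interval"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class SnakeConfig:
    """Active-contour parameters.

    alpha/beta are the contour's elasticity and rigidity weights, w_line /
    w_edge the attraction to bright intensity and to edges; iterations run
    in chunks until the mean vertex displacement per chunk drops below
    ``tol`` pixels or ``max_iterations`` is exhausted.
    """

    alpha: float = 0.015
    beta: float = 2.0
    w_line: float = 0.0
    w_edge: float = 1.0
    gamma: float = 0.001
    sigma: float = 2.0        # Gaussian pre-smoothing of the frame, px
    max_iterations: int = 4000
    chunk: int = 200
    tol: float = 0.1          # shape shift between same-parity chunks, px
    max_px_move: float = 0.2  # per-iteration vertex move cap, px
    n_init: int = 200         # vertices used during snake evolution


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any())


def _single_object_mask(mask: np.ndarray) -> np.ndarray:
    """Validate that the mask holds exactly one object and return it filled."""
    labels, n = ndi.label(mask > 0)
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= 9) + 1  # ignore sub-3x3-px specks
    if len(keep) == 0:
        raise AmbiguousSceneError("no object found in frame")
    if len(keep) > 1:
        raise AmbiguousSceneError(f"{len(keep)} objects found in frame; expected 1")
    return ndi.binary_fill_holes(labels == keep[0])


def mask_to_boundary(mask: np.ndarray, pixel_size: float, n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Trace the outline of a single-object binary mask.

    Returns an (n_points, 2) CCW equidistant boundary in µm (marching
    squares on the 0.5 level of the filled mask).
    """
    obj = _single_object_mask(np.asarray(mask))
    contours = measure.find_contours(obj.astype(float), 0.5)
    if not contours:
        raise AmbiguousSceneError("no contour found")
    contour = max(contours, key=len)[:-1]  # (row, col), drop repeated endpoint
    # marching squares staircases inflate the perimeter; a short cyclic
    # moving average (~2 px of arc) removes the stairs at sub-pixel cost
    if len(contour) >= 9:
        from scipy.ndimage import uniform_filter1d
        contour = uniform_filter1d(contour, 5, axis=0, mode="wrap")
    pts_um = np.column_stack([contour[:, 1], contour[:, 0]]) * pixel_size
    return resample_boundary(pts_um, n_points)


def _circle_seed(center_rc, radius_px, n):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center_rc[0] + radius_px * np.sin(t),
                            center_rc[1] + radius_px * np.cos(t)])


def extract_boundary(frame: np.ndarray,
                     init=None,
                     pixel_size: float = 1.0,
                     n_points: int = DEFAULT_N_POINTS,
                     config: SnakeConfig | None = None,
                     frame_index: int | None = None) -> np.ndarray:
    """Extract a closed cell boundary from one intensity frame with a snake.

    Parameters
    ----------
    frame : 2-D intensity array.
    init : optional snake seed — an (M, 2) boundary in µm (e.g. the
        previous frame's result).  If omitted, a circle around the single
        above-Otsu object is used.
    pixel_size : µm per pixel.
    n_points : vertices in the returned boundary.
    config : snake parameters.

    Returns an (n_points, 2) CCW equidistant boundary in µm.  Raises
    :class:`SegmentationError` if the snake does not converge and
    :class:`AmbiguousSceneError` if the scene has zero or several objects.
    """
    cfg = config or SnakeConfig()
    img = np.asarray(frame, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi > lo:
        img = (img - lo) / (hi - lo)
    smoothed = gaussian(img, sigma=cfg.sigma, preserve_range=True)

    # Validate the scene and build the seed in (row, col) pixel space.
    thresh = threshold_otsu(smoothed)
    obj = _single_object_mask(smoothed > thresh)
    if init is None:
        rc = np.argwhere(obj)
        center = rc.mean(axis=0)
        radius = np.sqrt(obj.sum() / np.pi) * 1.4 + 3.0
        snake = _circle_seed(center, radius, cfg.n_init)
    else:
        pts = np.asarray(init, dtype=float) / pixel_size  # µm -> px, (x, y)
        snake = np.column_stack([pts[:, 1], pts[:, 0]])
        if not obj[tuple(np.clip(np.round(snake.mean(axis=0)).astype(int), 0,
                                 np.array(obj.shape) - 1))]:
            # Seed centroid off the object: likely a scene/seed mismatch.
            raise AmbiguousSceneError("seed does not overlap the object")

    # Evolve in chunks and test shape convergence between chunks of the
    # same parity: the discrete snake settles into a small period-two
    # breathing cycle around the edge, and points slide tangentially even
    # at equilibrium, so the criterion is the nearest-vertex distance to
    # the shape two chunks ago.
    from scipy.spatial.distance import cdist
    iterations = 0
    converged = False
    history = [snake]
    while iterations < cfg.max_iterations:
        new = active_contour(smoothed, snake, alpha=cfg.alpha, beta=cfg.beta,
                             w_line=cfg.w_line, w_edge=cfg.w_edge,
                             gamma=cfg.gamma, max_num_iter=cfg.chunk,
                             max_px_move=cfg.max_px_move)
        history.append(new)
        snake = new
        iterations += cfg.chunk
        if len(history) >= 3:
            shift = float(cdist(new, history[-3]).min(axis=1).mean())
            if shift < cfg.tol:
                converged = True
                break
    if not converged:
        raise SegmentationError(
            f"snake did not converge within {cfg.max_iterations} iterations"
            + ("" if frame_index is None else f" (frame {frame_index})"),
            frame_index=frame_index)

    # average the last two chunks to cancel the residual breathing mode
    settled = 0.5 * (history[-1] + history[-2]) if len(history) >= 2 else snake
    pts_um = np.column_stack([settled[:, 1], settled[:, 0]]) * pixel_size
    return resample_boundary(pts_um, n_points)


def extract_movie(stack: FrameStack,
                  n_points: int = DEFAULT_N_POINTS,
                  mode: str = "auto",
                  config: SnakeConfig | None = None) -> BoundaryMovie:
    """Extract boundaries for every frame of a stack.

    ``mode`` is ``"mask"`` (contour tracing), ``"image"`` (snake, seeded
    frame-to-frame), or ``"auto"`` (mask route if the stack is binary).
    Frames where the object touches the image border are flagged on the
    returned movie rather than dropped.
    """
    frames = stack.frames
    if mode == "auto":
        vals = np.unique(frames)
        mode = "mask" if len(vals) <= 2 else "image"

    boundaries = np.empty((stack.n_frames, n_points, 2))
    flags = np.zeros(stack.n_frames, dtype=bool)
    failures = []
    prev = None
    for t in range(stack.n_frames):
        try:
            if mode == "mask":
                boundaries[t] = mask_to_boundary(frames[t], stack.pixel_size, n_points)
                flags[t] = _touches_border(frames[t] > 0)
            else:
                boundaries[t] = extract_boundary(frames[t], init=prev,
                                                 pixel_size=stack.pixel_size,
                                                 n_points=n_points, config=config,
                                                 frame_index=t)
                prev = boundaries[t]
        except (SegmentationError, AmbiguousSceneError, DegenerateBoundaryError) as exc:
            failures.append((t, str(exc)))
    if failures:
        msg = "; ".join(f"frame {t}: {m}" for t, m in failures)
        raise SegmentationError(f"unextractable frames: {msg}",
                                frame_index=failures[0][0])
    return BoundaryMovie(points=boundaries, frame_interval=stack.frame_interval,
                         border_flags=flags)
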