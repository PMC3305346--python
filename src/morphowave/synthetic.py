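"""Synthetic migrating-cell movies with per-stage ground truth.

The generator emulates the shape dynamics of a migrating amoeboid cell
(Dictyostelium-like): an elongated closed boundary whose front and back
carry persistent high curvature, localized curvature bumps born just off
the front that travel rearward along (typically alternating) sides at a
programmed arc speed while their amplitude decays, and steady centroid
translation.  An optional unpolarised round phase precedes migration,
with small transient non-traveling bumps standing in for the quickly
retracted exploratory protrusions of a resting cell.

Every stochastic choice flows from one seeded generator, and a log
records each bump's birth time, side and arc-length path, so detection
and speed estimates can be checked against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon

from .boundary import BoundaryMovie, resample_closed
from .segmentation import FrameStack


class SelfIntersectionError(ValueError):
    """Parameter combination drove the boundary through itself."""


@dataclass
class SyntheticCellSpec:
    """Parameters of the synthetic migrating cell.

    Units: µm, seconds, µm/min for speeds, events/min for rates.
    Defaults describe a typical polarised, migrating amoeboid cell:
    ~16 µm long axis, waves born just off the front about 3 times a
    minute, traveling rearward at 20 µm/min on alternating sides while
    the cell advances at 6 µm/min.
    """

    base_radius: float = 8.0          # µm, mean radius of the body
    elongation: float = 0.15          # front/back curvature contrast (cos 2θ term)
    wave_speed: float = 20.0          # µm/min rearward travel, relative to the cell
    wave_birth_rate: float = 3.0      # births/min
    alternation_prob: float = 0.9     # probability each birth switches side
    wave_amplitude: float = 1.5       # µm peak radial displacement
    wave_sigma: float = 1.5           # µm arc-length Gaussian half-width
    wave_growth_s: float = 10.0       # amplitude rise time constant, s
    wave_decay_s: float = 30.0        # amplitude decay time constant, s
    birth_offset: float = 0.5         # µm arc distance of births from the front apex
    birth_jitter: float = 0.3         # fractional jitter of inter-birth intervals
    centroid_speed: float = 6.0       # µm/min along +x
    frame_interval: float = 4.0       # s
    duration: float = 600.0           # s
    pixel_size: float = 0.2           # µm/px (rendering)
    n_points: int = 400
    seed: int = 0
    polarized_at: float | None = None  # s; None -> polarised from the start
    polarization_ramp_s: float = 60.0
    round_bump_amplitude: float = 0.5  # µm, pre-polarization transient bumps
    round_bump_lifetime_s: float = 8.0

    def __post_init__(self):
        for name in ("base_radius", "wave_speed", "wave_birth_rate",
                     "wave_amplitude", "centroid_speed", "frame_interval",
                     "duration", "pixel_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.alternation_prob <= 1.0:
            raise ValueError("alternation_prob must be in [0, 1]")
        if self.duration < 2 * self.frame_interval:
            raise ValueError("duration must cover at least 2 frames")


@dataclass
class GroundTruthLog:
    """Exact record of what the generator did.

    bumps: one row per bump (bump_id, birth_s, side, traveling,
    amplitude, arc_speed_um_min); paths: one row per bump per frame
    (bump_id, frame, time_s, arc_um signed from the front, amplitude).
    """

    spec: SyntheticCellSpec
    bumps: pd.DataFrame
    paths: pd.DataFrame
    centroids: np.ndarray  # (T, 2) programmed centroid path, µm

    def spec_dict(self) -> dict:
        return asdict(self.spec)


def _polarization(spec: SyntheticCellSpec, t_s: np.ndarray) -> np.ndarray:
    if spec.polarized_at is None:
        return np.ones_like(t_s)
    return np.clip((t_s - spec.polarized_at) / spec.polarization_ramp_s, 0.0, 1.0)


def _birth_times(rng, start, stop, rate_per_min, jitter):
    """Quasi-regular birth times: rate-determined intervals with jitter."""
    if rate_per_min <= 0 or stop <= start:
        return []
    mean_gap = 60.0 / rate_per_min
    times = []
    t = start + mean_gap * (0.5 + jitter * (rng.random() - 0.5))
    while t < stop:
        times.append(t)
        t += mean_gap * (1.0 + jitter * (rng.random() - 0.5))
    return times


def _amplitude(spec, age_s, traveling):
    if traveling:
        tg, td = spec.wave_growth_s, spec.wave_decay_s
        a0 = spec.wave_amplitude
    else:
        tg = spec.round_bump_lifetime_s * 0.3
        td = spec.round_bump_lifetime_s * 0.7
        a0 = spec.round_bump_amplitude
    return a0 * (1.0 - np.exp(-age_s / tg)) * np.exp(-age_s / td)


def generate_boundary_movie(spec: SyntheticCellSpec,
                            dense: int = 1024) -> tuple[BoundaryMovie, GroundTruthLog]:
    """Generate a boundary movie and its ground-truth log.

    Frames are returned as CCW, equidistant ``n_points``-vertex
    boundaries whose first vertex sits at the cell front (+x direction),
    so the kymograph row origin coincides with the front apex.
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = int(np.floor(spec.duration / spec.frame_interval))
    if n_frames < 2:
        raise ValueError("duration too short for 2 frames")
    t_s = np.arange(n_frames) * spec.frame_interval
    pol = _polarization(spec, t_s)

    # programmed centroid path: speed scales with the polarisation factor
    step = spec.centroid_speed / 60.0 * spec.frame_interval * pol
    cx = np.concatenate([[0.0], np.cumsum(step[:-1])])
    centroids = np.column_stack([cx, np.zeros(n_frames)])

    # bump schedule
    polar_start = 0.0 if spec.polarized_at is None else spec.polarized_at
    records = []
    if spec.polarized_at is not None:
        for bt in _birth_times(rng, 0.0, polar_start, spec.wave_birth_rate,
                               spec.birth_jitter):
            side = 1 if rng.random() < 0.5 else -1
            records.append({"birth_s": bt, "side": side, "traveling": False})
    side = 1 if rng.random() < 0.5 else -1
    for bt in _birth_times(rng, polar_start, spec.duration,
                           spec.wave_birth_rate, spec.birth_jitter):
        records.append({"birth_s": bt, "side": side, "traveling": True})
        if rng.random() < spec.alternation_prob:
            side = -side
    records.sort(key=lambda r: r["birth_s"])
    bumps = pd.DataFrame(records, columns=["birth_s", "side", "traveling"])
    bumps.insert(0, "bump_id", np.arange(len(bumps)))
    bumps["amplitude"] = np.where(bumps["traveling"], spec.wave_amplitude,
                                  spec.round_bump_amplitude)
    bumps["arc_speed_um_min"] = np.where(bumps["traveling"], spec.wave_speed, 0.0)

    theta = np.linspace(0.0, 2.0 * np.pi, dense, endpoint=False)
    boundaries = np.empty((n_frames, spec.n_points, 2))
    path_rows = []
    for f in range(n_frames):
        e = spec.elongation * pol[f]
        r0 = spec.base_radius * (1.0 + e * np.cos(2.0 * theta))
        # arc-length coordinate of the base contour, measured from θ=0 (front)
        dr = -2.0 * spec.base_radius * e * np.sin(2.0 * theta)
        ds = np.sqrt(r0 ** 2 + dr ** 2) * (2.0 * np.pi / dense)
        arc = np.concatenate([[0.0], np.cumsum(ds)])[:-1]
        perim = arc[-1] + ds[-1]

        delta = np.zeros(dense)
        for rec in bumps.itertuples():
            age = t_s[f] - rec.birth_s
            if age < 0:
                continue
            amp = _amplitude(spec, age, rec.traveling)
            if age > spec.wave_growth_s and amp < 0.02 * rec.amplitude:
                continue
            v_um_s = rec.arc_speed_um_min / 60.0
            p = rec.side * (spec.birth_offset + v_um_s * age)
            if abs(p) > 0.45 * perim:
                continue  # absorbed into the back
            d = (arc - (p % perim) + perim / 2.0) % perim - perim / 2.0
            delta += amp * np.exp(-0.5 * (d / spec.wave_sigma) ** 2)
            path_rows.append({"bump_id": rec.bump_id, "frame": f,
                              "time_s": t_s[f], "arc_um": p, "amplitude": amp})
        r = r0 + delta
        # the radial construction cannot represent overhangs, so bumps
        # comparable to the body radius mean the shape model has broken
        if r.min() <= 0.2 * spec.base_radius or delta.max() > 0.8 * spec.base_radius:
            raise SelfIntersectionError(
                "boundary deformation too large for a simple shape; reduce "
                f"wave_amplitude ({spec.wave_amplitude}) or increase "
                f"base_radius ({spec.base_radius})")
        pts = np.column_stack([centroids[f, 0] + r * np.cos(theta),
                               centroids[f, 1] + r * np.sin(theta)])
        boundaries[f] = resample_closed(pts, spec.n_points)

    movie = BoundaryMovie(points=boundaries, frame_interval=spec.frame_interval)
    paths = pd.DataFrame(path_rows,
                         columns=["bump_id", "frame", "time_s", "arc_um", "amplitude"])
    return movie, GroundTruthLog(spec=spec, bumps=bumps, paths=paths,
                                 centroids=centroids)


def match_tracks_to_bumps(tracks, truth: GroundTruthLog,
                          spacings: np.ndarray,
                          min_overlap: int = 3) -> pd.DataFrame:
    """Associate detected wave tracks with logged bumps by path overlap.

    For every track, the logged bump whose (frame -> boundary index) path
    lies closest to the track's samples over their common frames wins.
    Returns one row per matched track with the bump id, the programmed
    side/speed and the mean index distance of the match.
    """
    n = tracks[0].n_points if tracks else 0
    paths = {}
    for bid, g in truth.paths.groupby("bump_id"):
        idx = (g["arc_um"].to_numpy() / spacings[g["frame"].to_numpy()]) % n
        paths[bid] = dict(zip(g["frame"].to_numpy(), idx))
    rows = []
    for k, tr in enumerate(tracks):
        best = None
        for bid, path in paths.items():
            common = [(f, i) for f, i in zip(tr.frames.astype(int), tr.indices % n)
                      if f in path]
            if len(common) < min_overlap:
                continue
            d = np.mean([abs(float((i - path[f] + n / 2) % n - n / 2))
                         for f, i in common])
            if best is None or d < best[1]:
                best = (bid, d)
        if best is None:
            continue
        bump = truth.bumps.set_index("bump_id").loc[best[0]]
        rows.append({"track_id": k, "bump_id": int(best[0]),
                     "mean_index_distance": best[1],
                     "true_side": "left" if bump["side"] > 0 else "right",
                     "detected_side": tr.side,
                     "side_match": (tr.side == ("left" if bump["side"] > 0 else "right")),
                     "true_speed_um_min": float(bump["arc_speed_um_min"])})
    return pd.DataFrame(rows, columns=["track_id", "bump_id", "mean_index_distance",
                                       "true_side", "detected_side", "side_match",
                                       "true_speed_um_min"])


@dataclass
class RenderedMovie:
    """Rasterised output of a boundary movie.

    masks / fluorescence: FrameStacks sharing one image geometry;
    origin_um: (x, y) of the image's top-left pixel centre in boundary
    coordinates — add it to re-extracted boundaries to compare with the
    generated ones.
    """

    masks: FrameStack
    fluorescence: FrameStack
    origin_um: tuple[float, float]


def render_movie(movie: BoundaryMovie, spec: SyntheticCellSpec,
                 shape: tuple[int, int] | None = None,
                 margin_um: float = 2.0,
                 photons: float = 200.0,
                 blur_px: float = 1.5) -> RenderedMovie:
    """Rasterise a boundary movie into mask and pseudo-fluorescence stacks.

    Masks are filled polygons at ``spec.pixel_size``; fluorescence is the
    mask blurred and degraded with Poisson shot noise at ``photons``
    expected counts inside the cell.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed + 1)
    pts = movie.points
    x0 = pts[..., 0].min() - margin_um
    y0 = pts[..., 1].min() - margin_um
    if shape is None:
        w = int(np.ceil((pts[..., 0].max() + margin_um - x0) / spec.pixel_size)) + 1
        h = int(np.ceil((pts[..., 1].max() + margin_um - y0) / spec.pixel_size)) + 1
        shape = (h, w)
    masks = np.zeros((movie.n_frames, *shape), dtype=np.uint8)
    fluor = np.zeros((movie.n_frames, *shape), dtype=float)
    for f in range(movie.n_frames):
        cols = (pts[f, :, 0] - x0) / spec.pixel_size
        rows = (pts[f, :, 1] - y0) / spec.pixel_size
        if cols.min() < 0 or rows.min() < 0 or cols.max() > shape[1] - 1 or rows.max() > shape[0] - 1:
            raise ValueError(f"cell exceeds the frame at frame {f}; enlarge shape")
        rr, cc = draw_polygon(rows, cols, shape=shape)
        masks[f, rr, cc] = 1
        img = gaussian_filter(masks[f].astype(float), blur_px) * photons
        fluor[f] = rng.poisson(img).astype(float)
    cal = dict(pixel_size=spec.pixel_size, frame_interval=spec.frame_interval)
    return RenderedMovie(masks=FrameStack(masks, **cal),
                         fluorescence=FrameStack(fluor, **cal),
                         origin_um=(float(x0), float(y0)))
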