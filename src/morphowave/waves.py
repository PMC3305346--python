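"""Traveling curvature-wave detection and speed estimation.

In a curvature kymograph of a polarised cell the front and back appear
as two thick, persistent high-curvature bands, while traveling waves
appear as thin tilted lines connecting them.  The tracker excludes the
two persistent bands, finds per-frame local maxima along the cyclic
point axis, links them across frames by nearest index, and fits a robust
line to each linked ridge.  Speeds are reported both relative to the
cell (index slope x point spacing) and relative to the substrate (lab
frame motion of the ridge positions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import theilslopes

from .boundary import cyclic_index_difference
from .kymograph import ScalarKymograph
from .motion import MotionField
from .tracking import TrackedBoundarySeries


@dataclass
class WaveTrackParams:
    """Ridge-tracker settings.

    amplitude_threshold: minimum peak value; None -> robust floor
        (median + 2 scaled MADs of the band-excluded kymograph).
    max_jump: largest allowed index step per frame when linking peaks.
        Scale it to the fastest expected wave: ceil(v_max * dt / spacing).
    min_length: minimum track duration in frames.
    band_margin: half-width (indices) of the excluded front/back bands.
    max_gap: frames a track may go undetected before it is closed.
    min_slope: smallest |index slope| (indices/frame) that counts as
        traveling; persistent stationary ripples are not waves.
    """

    amplitude_threshold: float | None = None
    max_jump: int = 10
    min_length: int = 5
    band_margin: int = 15
    max_gap: int = 1
    min_slope: float = 0.5


@dataclass
class WaveTrack:
    """One linked kymograph ridge.

    ``indices`` are cyclically unwrapped (they may leave [0, N) to keep
    the trajectory continuous); ``side`` is ``"left"`` for increasing
    index and ``"right"`` for decreasing, relative to the boundary
    orientation.
    """

    frames: np.ndarray
    indices: np.ndarray
    values: np.ndarray
    n_points: int
    speed_cell: float | None = None
    speed_substrate: float | None = None

    @property
    def birth_frame(self) -> int:
        return int(self.frames[0])

    @property
    def birth_index(self) -> int:
        return int(round(self.indices[0])) % self.n_points

    @property
    def index_slope(self) -> float:
        if len(self.frames) < 2:
            return 0.0
        return float(theilslopes(self.indices, self.frames)[0])

    @property
    def side(self) -> str:
        return "left" if self.index_slope >= 0 else "right"


def find_front_back_bands(kymo: ScalarKymograph) -> tuple[int, int]:
    """Indices of the two persistent high-curvature plateaus (front, back).

    The two largest maxima of the time-averaged profile separated by at
    least N/4 indices.  The median over time is used as the average:
    transient wave traffic passes any index only a minority of the time,
    so the median isolates the persistent plateaus.
    """
    profile = np.median(kymo.matrix, axis=1)
    n = len(profile)
    i1 = int(np.argmax(profile))
    d = np.abs(cyclic_index_difference(np.arange(n), i1, n))
    masked = np.where(d >= n / 4, profile, -np.inf)
    i2 = int(np.argmax(masked))
    return i1, i2


def _band_mask(n: int, centers, margin: int) -> np.ndarray:
    """Boolean mask, True at indices within ``margin`` of any centre."""
    idx = np.arange(n)
    mask = np.zeros(n, dtype=bool)
    for c in centers:
        mask |= np.abs(cyclic_index_difference(idx, c, n)) <= margin
    return mask


def _cyclic_peaks(column: np.ndarray, exclude: np.ndarray, threshold: float) -> np.ndarray:
    """Strict local maxima along a cyclic 1-D profile above a threshold."""
    up = column > np.roll(column, 1)
    down = column > np.roll(column, -1)
    peaks = up & down & (column > threshold) & ~exclude
    return np.flatnonzero(peaks)


def default_amplitude_threshold(kymo: ScalarKymograph, exclude: np.ndarray | None = None) -> float:
    """Robust amplitude floor: median + 2 x 1.4826 x MAD."""
    vals = kymo.matrix if exclude is None else kymo.matrix[~exclude, :]
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    return float(med + 2.0 * 1.4826 * mad)


def detect_wave_tracks(kymo: ScalarKymograph,
                       params: WaveTrackParams | None = None) -> list[WaveTrack]:
    """Detect traveling ridges in a kymograph.

    Per frame, strict local maxima along the cyclic point axis above the
    amplitude threshold (outside the persistent front/back bands) are
    linked to the nearest active track within ``max_jump`` indices per
    frame; tracks shorter than ``min_length`` frames are discarded.
    """
    p = params or WaveTrackParams()
    if kymo.n_frames < 10:
        raise ValueError("need a kymograph of at least 10 frames")
    n = kymo.n_points
    bands = find_front_back_bands(kymo)
    exclude = _band_mask(n, bands, p.band_margin)
    threshold = (p.amplitude_threshold if p.amplitude_threshold is not None
                 else default_amplitude_threshold(kymo, exclude))

    active: list[dict] = []
    done: list[dict] = []
    for t in range(kymo.n_frames):
        peaks = _cyclic_peaks(kymo.matrix[:, t], exclude, threshold)
        # candidate (track, peak) pairs ordered by cyclic distance
        pairs = []
        for ti, tr in enumerate(active):
            gap = t - tr["frames"][-1]
            for pi, pk in enumerate(peaks):
                d = abs(cyclic_index_difference(pk, tr["indices"][-1] % n, n))
                if d <= p.max_jump * gap:
                    pairs.append((d, ti, pi))
        pairs.sort()
        used_tracks, used_peaks = set(), set()
        for d, ti, pi in pairs:
            if ti in used_tracks or pi in used_peaks:
                continue
            used_tracks.add(ti)
            used_peaks.add(pi)
            tr = active[ti]
            step = cyclic_index_difference(peaks[pi], tr["indices"][-1] % n, n)
            tr["frames"].append(t)
            tr["indices"].append(tr["indices"][-1] + float(step))
            tr["values"].append(kymo.matrix[peaks[pi], t])
        for pi, pk in enumerate(peaks):
            if pi not in used_peaks:
                active.append({"frames": [t], "indices": [float(pk)],
                               "values": [kymo.matrix[pk, t]]})
        still = []
        for tr in active:
            if t - tr["frames"][-1] > p.max_gap:
                done.append(tr)
            else:
                still.append(tr)
        active = still
    done.extend(active)

    tracks = [WaveTrack(frames=np.array(tr["frames"]),
                        indices=np.array(tr["indices"]),
                        values=np.array(tr["values"]), n_points=n)
              for tr in done if len(tr["frames"]) >= p.min_length]
    tracks = [tr for tr in tracks if abs(tr.index_slope) >= p.min_slope]
    tracks.sort(key=lambda tr: (tr.birth_frame, tr.birth_index))
    return tracks


def wave_speed(track: WaveTrack,
               series: TrackedBoundarySeries) -> tuple[float, float]:
    """Speed of a ridge relative to the cell and to the substrate (µm/min).

    speed_cell: |d(index)/d(frame)| (Theil-Sen fit) x mean point spacing
    of the spanned frames x 60/frame_interval.  speed_substrate: robust
    fit of the ridge's lab-frame (x, y) positions against time.
    """
    if len(track.frames) < 3:
        raise ValueError("need at least 3 samples to fit a speed")
    if track.frames[-1] == track.frames[0]:
        raise ValueError("zero-duration track")
    dt = series.frame_interval
    spans = series.spacings()[track.frames.astype(int)]
    slope = abs(track.index_slope)
    speed_cell = slope * float(spans.mean()) * 60.0 / dt

    idx = np.round(track.indices).astype(int) % track.n_points
    pos = series.points[track.frames.astype(int), idx]
    tsec = track.frames * dt
    vx = theilslopes(pos[:, 0], tsec)[0]
    vy = theilslopes(pos[:, 1], tsec)[0]
    speed_substrate = float(np.hypot(vx, vy)) * 60.0
    track.speed_cell = speed_cell
    track.speed_substrate = speed_substrate
    return speed_cell, speed_substrate


def overlay_tracks(curv_kymo: ScalarKymograph,
                   motion: MotionField | ScalarKymograph,
                   tracks: list[WaveTrack]) -> pd.DataFrame:
    """Motion context at each wave's birth.

    Returns one row per track with the local-motion value at its first
    sample; ``frac_born_protrusive`` (fraction of tracks born where the
    motion is positive) is stored in ``DataFrame.attrs``.
    """
    mkymo = motion.to_kymograph() if isinstance(motion, MotionField) else motion
    if mkymo.n_points != curv_kymo.n_points:
        raise ValueError("kymographs do not share a point axis")
    rows = []
    for k, tr in enumerate(tracks):
        t0 = min(tr.birth_frame, mkymo.n_frames - 1)
        mval = float(mkymo.matrix[tr.birth_index, t0])
        rows.append({"track_id": k, "birth_frame": tr.birth_frame,
                     "birth_index": tr.birth_index, "birth_motion": mval,
                     "protrusive_birth": mval > 0.0})
    df = pd.DataFrame(rows, columns=["track_id", "birth_frame", "birth_index",
                                     "birth_motion", "protrusive_birth"])
    df.attrs["frac_born_protrusive"] = float(df["protrusive_birth"].mean()) if len(df) else np.nan
    return df


def tracks_to_frame(tracks: list[WaveTrack],
                    series: TrackedBoundarySeries | None = None) -> pd.DataFrame:
    """Long-format table of track samples (one row per frame per track)."""
    rows = []
    for k, tr in enumerate(tracks):
        for f, i, v in zip(tr.frames, tr.indices, tr.values):
            row = {"track_id": k, "frame": int(f),
                   "boundary_index": int(round(i)) % tr.n_points, "value": v}
            if series is not None:
                xy = series.points[int(f), row["boundary_index"]]
                row["x_um"], row["y_um"] = xy
            rows.append(row)
    return pd.DataFrame(rows)


def tracks_from_frame(df: pd.DataFrame, n_points: int) -> list[WaveTrack]:
    """Rebuild tracks from a long-format table (e.g. manually drawn ones)."""
    tracks = []
    for _, g in df.groupby("track_id"):
        g = g.sort_values("frame")
        raw = g["boundary_index"].to_numpy(dtype=float)
        unwrapped = raw.copy()
        for i in range(1, len(raw)):
            unwrapped[i] = unwrapped[i - 1] + cyclic_index_difference(
                raw[i], raw[i - 1], n_points)
        tracks.append(WaveTrack(frames=g["frame"].to_numpy(),
                                indices=unwrapped,
                                values=g.get("value", pd.Series(np.zeros(len(g)))).to_numpy(),
                                n_points=n_points))
    return tracks
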