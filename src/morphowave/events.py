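"""Discrete protrusion/retraction events and boundary MSD.

Individual protrusions and retractions are the peaks and valleys of the
local motion measure: strict space-time local extrema above a noise
threshold.  Continuous protrusive activity is summarised by the circular
weighted-mean location of positive motion per frame, and the mean
squared displacement of that location along the boundary separates a
short-lag ballistic regime (log-log slope ~2, wave-like travel) from a
long-lag caged regime (slope ~0, confinement to the front).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter

from .boundary import cyclic_index_difference
from .motion import MotionField


@dataclass
class EventParams:
    """Peak/valley extraction settings.

    threshold: minimum |motion| (µm per lag); None -> robust floor from
        the field itself (median + 3 scaled MADs of |values|).
    space_halfwidth / time_halfwidth: half-sizes of the 2-D neighbourhood
        an extremum must dominate (default +-7 indices x +-1 frame).
    """

    threshold: float | None = None
    space_halfwidth: int = 7
    time_halfwidth: int = 1


@dataclass
class EventSet:
    """Discrete events: one row per (frame, boundary index) extremum."""

    events: pd.DataFrame  # columns: frame, boundary_index, magnitude, type
    duration_min: float
    n_points: int

    def __len__(self) -> int:
        return len(self.events)

    def of_type(self, kind: str) -> pd.DataFrame:
        return self.events[self.events["type"] == kind]

    def rate(self, kind: str) -> float:
        """Events per minute for 'protrusion' or 'retraction'."""
        return len(self.of_type(kind)) / self.duration_min


def default_event_threshold(field: MotionField) -> float:
    """Noise floor estimated from the quiet part of the field itself.

    Most of the boundary of even an active cell is quiet at any instant,
    so the RMS of the |motion| values below their median estimates the
    noise process; the floor is 3 x that RMS (the same rule
    :func:`morphowave.motion.calibrate_noise_threshold` applies to a
    static calibration movie).
    """
    mag = np.abs(field.values)
    quiet = mag[mag <= np.median(mag)]
    return float(3.0 * np.sqrt(np.mean(quiet ** 2)))


def _strict_local_maxima(values: np.ndarray, shw: int, thw: int) -> np.ndarray:
    """Boolean mask of strict 2-D local maxima (cyclic space, clipped time)."""
    footprint = np.ones((2 * shw + 1, 2 * thw + 1), dtype=bool)
    footprint[shw, thw] = False  # exclude the centre: strictness
    padded = np.pad(values, ((shw, shw), (0, 0)), mode="wrap")
    neigh = maximum_filter(padded, footprint=footprint, mode="nearest")[shw:-shw]
    return values > neigh


def extract_events(field: MotionField,
                   params: EventParams | None = None) -> EventSet:
    """Protrusions (peaks) and retractions (valleys) of the motion field.

    An event is a strict local extremum of the N x T' field over a
    space-time neighbourhood whose |magnitude| exceeds the threshold;
    plateaus (ties) never produce events, so steady translation does not
    register.  Events are sorted by frame, then index.
    """
    p = params or EventParams()
    thr = p.threshold if p.threshold is not None else default_event_threshold(field)
    rows = []
    for kind, sgn in (("protrusion", 1.0), ("retraction", -1.0)):
        v = sgn * field.values
        mask = _strict_local_maxima(v, p.space_halfwidth, p.time_halfwidth) & (v > thr)
        idx, frm = np.nonzero(mask)
        for i, t in zip(idx, frm):
            rows.append({"frame": int(t), "boundary_index": int(i),
                         "magnitude": float(field.values[i, t]), "type": kind})
    df = pd.DataFrame(rows, columns=["frame", "boundary_index", "magnitude", "type"])
    df = df.sort_values(["frame", "boundary_index"], kind="stable").reset_index(drop=True)
    return EventSet(events=df, duration_min=field.duration_min,
                    n_points=field.n_points)


def event_rates(event_sets, durations_min=None) -> dict:
    """Per-minute protrusion/retraction rates, with SEM across movies.

    Accepts one EventSet or a sequence of them (optionally with explicit
    durations).  With several movies the mean rate and the standard error
    of the mean across movies are reported.
    """
    if isinstance(event_sets, EventSet):
        event_sets = [event_sets]
    if durations_min is None:
        durations_min = [es.duration_min for es in event_sets]
    out = {}
    for kind in ("protrusion", "retraction"):
        rates = np.array([len(es.of_type(kind)) / d
                          for es, d in zip(event_sets, durations_min)])
        sem = (float(np.std(rates, ddof=1) / np.sqrt(len(rates)))
               if len(rates) > 1 else np.nan)
        out[f"{kind}_rate_per_min"] = float(rates.mean())
        out[f"{kind}_rate_sem"] = sem
    return out


@dataclass
class MeanLocationTrace:
    """Circular mean location of protrusive (or retractive) motion.

    index_location: fractional boundary index per frame (NaN where
    undefined); defined_mask: frames where the weighted activity cleared
    the noise floor and the circular mean was non-degenerate;
    point_spacing: per-frame mean spacing (µm) used to convert index
    displacements to arc length.
    """

    index_location: np.ndarray
    defined_mask: np.ndarray
    n_points: int
    point_spacing: np.ndarray
    frame_interval: float

    def arc_location(self) -> np.ndarray:
        return self.index_location * self.point_spacing


def mean_protrusion_location(field: MotionField,
                             threshold: float = 0.0,
                             kind: str = "protrusion",
                             min_resultant: float = 0.1) -> MeanLocationTrace:
    """Weighted circular mean of the motion's location, per frame.

    Weights are ``max(motion, 0)`` for protrusive and ``max(-motion, 0)``
    for retractive activity.  Indices are averaged as angles on the unit
    circle; a frame is undefined when the peak activity is below the
    noise ``threshold`` or when the resultant length (normalised) falls
    below ``min_resultant`` (e.g. antipodal activity).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    v = field.values if kind == "protrusion" else -field.values
    w = np.clip(v, 0.0, None)  # (N, T')
    n = field.n_points
    angles = 2.0 * np.pi * np.arange(n) / n
    z = (w * np.exp(1j * angles)[:, None]).sum(axis=0)
    wsum = w.sum(axis=0)
    peak = v.max(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        resultant = np.abs(z) / wsum
    defined = (wsum > 0) & (peak > threshold) & (resultant >= min_resultant)
    loc = np.full(field.n_frames, np.nan)
    loc[defined] = (np.angle(z[defined]) % (2.0 * np.pi)) * n / (2.0 * np.pi)
    return MeanLocationTrace(index_location=loc, defined_mask=defined,
                             n_points=n, point_spacing=field.point_spacing,
                             frame_interval=field.frame_interval)


@dataclass
class MSDResult:
    """Boundary-arc-length MSD of a location trace with regime analysis.

    lags_s / msd_um2 / n_pairs: the MSD curve; slope_short and slope_long
    are log-log slopes over the short- and long-lag windows; crossover_s
    is the first lag where the local log-log slope drops below 1;
    min_speed_um_min = sqrt(MSD(tau0)) / tau0, a lower bound on the speed
    of the underlying traveling activity.
    """

    lags_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray
    slope_short: float
    slope_long: float
    crossover_s: float
    min_speed_um_min: float


def _loglog_slope(lags, msd, lo, hi):
    sel = (lags >= lo) & (lags <= hi) & (msd > 0)
    if sel.sum() < 2:
        return np.nan
    return float(np.polyfit(np.log(lags[sel]), np.log(msd[sel]), 1)[0])


def boundary_msd(trace: MeanLocationTrace,
                 short_lag_s: tuple[float, float] = (4.0, 16.0),
                 long_lag_min_s: float = 60.0,
                 speed_lag_s: float = 8.0,
                 max_lag_frac: float = 0.5) -> MSDResult:
    """MSD of a boundary location along the boundary (arc length, µm²).

    Per-frame displacements are the shortest cyclic index differences
    between consecutive defined frames, converted to µm with the
    per-frame mean point spacing and accumulated along defined stretches;
    undefined frames break the accumulation.  MSD(tau) averages squared
    displacements over all frame pairs at lag tau within stretches.
    """
    loc = trace.index_location
    defined = trace.defined_mask
    if defined.sum() < 10:
        raise ValueError("need at least 10 defined frames")
    dt = trace.frame_interval
    n = trace.n_points

    # accumulate arc-length positions over contiguous defined runs
    runs = []
    start = None
    for t in range(len(loc) + 1):
        ok = t < len(loc) and defined[t]
        if ok and start is None:
            start = t
        elif not ok and start is not None:
            runs.append((start, t))
            start = None
    positions = []
    for a, b in runs:
        idx = loc[a:b]
        steps = cyclic_index_difference(idx[1:], idx[:-1], n)
        arc_steps = steps * trace.point_spacing[a + 1:b]
        pos = np.concatenate([[0.0], np.cumsum(arc_steps)])
        positions.append(pos)

    max_lag = max(int(max(len(p) for p in positions) * max_lag_frac), 2)
    lags = np.arange(1, max_lag)
    msd = np.zeros(len(lags))
    npairs = np.zeros(len(lags), dtype=int)
    for pos in positions:
        m = len(pos)
        for k, lag in enumerate(lags):
            if lag >= m:
                break
            d = pos[lag:] - pos[:-lag]
            msd[k] += np.sum(d * d)
            npairs[k] += len(d)
    valid = npairs > 0
    lags_s = lags[valid] * dt
    msd = msd[valid] / npairs[valid]
    npairs = npairs[valid]

    slope_short = _loglog_slope(lags_s, msd, *short_lag_s)
    slope_long = _loglog_slope(lags_s, msd, long_lag_min_s, lags_s.max() if len(lags_s) else 0)

    # crossover: first lag where the centred local log-log slope falls below 1
    crossover = np.nan
    pos_msd = msd > 0
    if pos_msd.sum() >= 3:
        lg, lm = np.log(lags_s[pos_msd]), np.log(msd[pos_msd])
        local = np.gradient(lm, lg)
        below = np.flatnonzero(local < 1.0)
        if len(below):
            crossover = float(lags_s[pos_msd][below[0]])

    k0 = np.argmin(np.abs(lags_s - speed_lag_s)) if len(lags_s) else None
    min_speed = (float(np.sqrt(msd[k0]) / lags_s[k0] * 60.0)
                 if k0 is not None and msd[k0] > 0 else np.nan)
    return MSDResult(lags_s=lags_s, msd_um2=msd, n_pairs=npairs,
                     slope_short=slope_short, slope_long=slope_long,
                     crossover_s=crossover, min_speed_um_min=min_speed)
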