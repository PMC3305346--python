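"""Readers and writers for the pipeline's file dialects.

Boundary tables are CSV with columns ``frame, point_index, x_um, y_um``
(plus ``global_index`` once tracked); kymographs are CSV matrices with
one row per boundary index and one column per frame.  Image stacks are
multi-page TIFF read/written with tifffile.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .boundary import BoundaryMovie
from .kymograph import ScalarKymograph
from .segmentation import FrameStack
from .tracking import TrackedBoundarySeries

BOUNDARY_COLUMNS = ["frame", "point_index", "x_um", "y_um"]


def read_tiff_stack(path, pixel_size: float, frame_interval: float) -> FrameStack:
    frames = tifffile.imread(str(path))
    if frames.ndim == 2:
        frames = frames[None]
    return FrameStack(frames=frames, pixel_size=pixel_size,
                      frame_interval=frame_interval)


def write_tiff_stack(path, stack: FrameStack) -> None:
    tifffile.imwrite(str(path), np.asarray(stack.frames))


def write_boundaries(path, movie: BoundaryMovie | TrackedBoundarySeries) -> None:
    T, n = movie.points.shape[:2]
    df = pd.DataFrame({
        "frame": np.repeat(np.arange(T), n),
        "point_index": np.tile(np.arange(n), T),
        "x_um": movie.points[:, :, 0].ravel(),
        "y_um": movie.points[:, :, 1].ravel(),
    })
    if isinstance(movie, TrackedBoundarySeries):
        # after tracking, the row order already is the global numbering
        df["global_index"] = np.tile(np.arange(n), T)
    df.to_csv(path, index=False)


def read_boundaries(path, frame_interval: float) -> BoundaryMovie:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in BOUNDARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"boundary CSV missing columns: {missing}")
    frames = np.sort(df["frame"].unique())
    counts = df.groupby("frame").size()
    if counts.nunique() != 1:
        raise ValueError("all frames must have the same number of points")
    n = int(counts.iloc[0])
    pts = np.empty((len(frames), n, 2))
    for k, f in enumerate(frames):
        g = df[df["frame"] == f].sort_values("point_index")
        pts[k, :, 0] = g["x_um"].to_numpy()
        pts[k, :, 1] = g["y_um"].to_numpy()
    return BoundaryMovie(points=pts, frame_interval=frame_interval)


def write_offsets(path, series: TrackedBoundarySeries) -> None:
    pd.DataFrame({"frame": np.arange(series.n_frames),
                  "offset": series.offsets}).to_csv(path, index=False)


def write_kymograph(path, kymo: ScalarKymograph) -> None:
    df = pd.DataFrame(kymo.matrix,
                      columns=[f"frame_{t}" for t in range(kymo.n_frames)])
    df.insert(0, "boundary_index", np.arange(kymo.n_points))
    df.to_csv(path, index=False)


def read_kymograph(path, quantity: str, point_spacing, frame_interval: float) -> ScalarKymograph:
    df = pd.read_csv(path, float_precision="round_trip")
    mat = df[[c for c in df.columns if c.startswith("frame_")]].to_numpy()
    return ScalarKymograph(matrix=mat, quantity=quantity,
                           point_spacing=point_spacing,
                           frame_interval=frame_interval)


def write_summary(path, summary: dict) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True,
                                     default=_default, allow_nan=True) + "\n")


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(path, data: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
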