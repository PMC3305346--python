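"""End-to-end analysis pipeline.

``run_pipeline`` ties the stages together: boundary extraction (or
simulation), point tracking, curvature and local-motion kymographs, wave
tracking, event extraction and the boundary MSD, writing a reproducible
output bundle (CSV/PNG/JSON, the resolved config, and a run log).
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import events as ev
from . import io as mio
from . import motion as mo
from . import shape_metrics as sm
from .kymograph import smooth_kymograph
from . import waves as wv
from .config import RunConfig
from .segmentation import SnakeConfig, extract_movie
from .synthetic import SyntheticCellSpec, generate_boundary_movie, render_movie
from .tracking import track_series

log = logging.getLogger("morphowave")


class CalibrationError(ValueError):
    pass


def _load_movie(cfg: RunConfig):
    if cfg.mode == "simulate":
        spec = SyntheticCellSpec(seed=cfg.seed, n_points=cfg.n_points,
                                 **cfg.simulate)
        movie, truth = generate_boundary_movie(spec)
        return movie, truth
    if cfg.input is None:
        raise ValueError("input path required for non-simulate modes")
    if cfg.mode == "boundary-csv":
        if cfg.frame_interval_s is None:
            raise CalibrationError("frame_interval_s is required for boundary CSV input")
        return mio.read_boundaries(cfg.input, cfg.frame_interval_s), None
    if cfg.pixel_size_um is None or cfg.frame_interval_s is None:
        raise CalibrationError(
            "pixel_size_um and frame_interval_s are required for image/mask input")
    stack = mio.read_tiff_stack(cfg.input, cfg.pixel_size_um, cfg.frame_interval_s)
    snake = SnakeConfig(**cfg.snake) if cfg.snake else None
    movie = extract_movie(stack, n_points=cfg.n_points, mode=cfg.mode, config=snake)
    return movie, None


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the output bundle.

    Returns the summary dictionary (also written to ``summary.json``).
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(cfg, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, out: Path) -> dict:
    from .plotting import save_kymograph_png

    digest = cfg.digest()
    cfg.to_yaml(out / "config_resolved.yaml")
    log.info("run %s: mode=%s input=%s", digest, cfg.mode, cfg.input)

    movie, truth = _load_movie(cfg)
    series = track_series(movie)
    mio.write_boundaries(out / "boundaries.csv", series)
    mio.write_offsets(out / "offsets.csv", series)

    # raw curvature for analysis; the 3x3-smoothed copy is for display/export
    curv = sm.curvature_kymograph(series, halfwidth=cfg.curvature_halfwidth,
                                  smooth=None)
    curv_display = (smooth_kymograph(curv, *cfg.curvature_smoothing)
                    if cfg.curvature_smoothing else curv)
    mio.write_kymograph(out / "curvature_kymograph.csv", curv_display)
    save_kymograph_png(out / "curvature_kymograph.png", curv_display,
                       cutoff=cfg.curvature_cutoff)

    polar = sm.polarization_trace(series)

    field = mo.local_motion(series, lag_s=cfg.motion_lag_s,
                            smoothing_windows=cfg.motion_smoothing,
                            smoothing_domain=cfg.motion_smoothing_domain)
    mkymo = field.to_kymograph()
    mio.write_kymograph(out / "motion_kymograph.csv", mkymo)
    save_kymograph_png(out / "motion_kymograph.png", mkymo, cutoff=cfg.motion_cutoff)

    wave_params = wv.WaveTrackParams(amplitude_threshold=cfg.wave_amplitude_threshold,
                                     max_jump=cfg.wave_max_jump,
                                     min_length=cfg.wave_min_length,
                                     band_margin=cfg.wave_band_margin)
    tracks = wv.detect_wave_tracks(curv, wave_params)
    speeds = [wv.wave_speed(tr, series) for tr in tracks]
    tdf = wv.tracks_to_frame(tracks, series)
    tdf.to_csv(out / "wave_tracks.csv", index=False)
    assoc = wv.overlay_tracks(curv, field, tracks)
    assoc.to_csv(out / "wave_birth_motion.csv", index=False)
    save_kymograph_png(out / "curvature_kymograph_tracks.png", curv_display,
                       cutoff=cfg.curvature_cutoff, tracks=tracks)

    eparams = ev.EventParams(threshold=cfg.event_threshold,
                             space_halfwidth=cfg.event_space_halfwidth,
                             time_halfwidth=cfg.event_time_halfwidth)
    eset = ev.extract_events(field, eparams)
    edf = eset.events.copy()
    if len(edf):
        xy = series.points[edf["frame"].to_numpy(), edf["boundary_index"].to_numpy()]
        edf["x_um"], edf["y_um"] = xy[:, 0], xy[:, 1]
    edf.to_csv(out / "events.csv", index=False)
    rates = ev.event_rates(eset)

    msd_summary = {}
    trace = ev.mean_protrusion_location(field,
                                        threshold=cfg.event_threshold or 0.0)
    if trace.defined_mask.sum() >= 10:
        msd = ev.boundary_msd(trace)
        np.savetxt(out / "msd.csv",
                   np.column_stack([msd.lags_s, msd.msd_um2, msd.n_pairs]),
                   delimiter=",", header="lag_s,msd_um2,n_pairs", comments="")
        msd_summary = {"msd_slope_short": msd.slope_short,
                       "msd_slope_long": msd.slope_long,
                       "msd_crossover_s": msd.crossover_s,
                       "msd_min_speed_um_min": msd.min_speed_um_min}

    summary = {
        "config_digest": digest,
        "n_frames": series.n_frames,
        "n_points": series.n_points,
        "mean_non_circularity": float(np.mean(polar.non_circularity)),
        "non_circularity": polar.non_circularity,
        "mean_centroid_speed_um_min": float(np.nanmean(polar.centroid_speed)),
        "n_wave_tracks": len(tracks),
        "wave_speed_cell_um_min": [s[0] for s in speeds],
        "wave_speed_substrate_um_min": [s[1] for s in speeds],
        "mean_wave_speed_cell_um_min": (float(np.mean([s[0] for s in speeds]))
                                        if speeds else None),
        "frac_waves_born_protrusive": assoc.attrs.get("frac_born_protrusive"),
        **rates,
        **msd_summary,
    }
    if truth is not None:
        truth.bumps.to_csv(out / "ground_truth_bumps.csv", index=False)
        truth.paths.to_csv(out / "ground_truth_paths.csv", index=False)
        summary["programmed"] = {k: v for k, v in asdict(truth.spec).items()}
    mio.write_summary(out / "summary.json", summary)
    log.info("run %s complete: %d wave tracks, %.2f protrusions/min",
             digest, len(tracks), rates["protrusion_rate_per_min"])
    return summary
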