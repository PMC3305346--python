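"""Run configuration: one record of every pipeline parameter.

Defaults reproduce the standard analysis constants: 400 boundary points,
circle-fit curvature over a +-10-point stencil smoothed 3x3, a 12-s
motion lag with 19- and 15-point mapping smoothing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

from . import io as mio


@dataclass
class RunConfig:
    input: str | None = None
    mode: str = "simulate"            # image | mask | boundary-csv | simulate
    output_dir: str = "morphowave_out"
    pixel_size_um: float | None = None
    frame_interval_s: float | None = None
    n_points: int = 400
    curvature_halfwidth: int = 10
    curvature_smoothing: tuple[int, int] = (3, 3)
    motion_lag_s: float = 12.0
    motion_smoothing: tuple[int, int] = (19, 15)
    motion_smoothing_domain: str = "index"
    wave_max_jump: int = 10
    wave_min_length: int = 5
    wave_band_margin: int = 15
    wave_amplitude_threshold: float | None = None
    event_threshold: float | None = None
    event_space_halfwidth: int = 7
    event_time_halfwidth: int = 1
    curvature_cutoff: float = 1.5     # plotting colour-scale cutoff, 1/µm
    motion_cutoff: float | None = None
    seed: int = 0
    snake: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)  # SyntheticCellSpec overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = mio.load_yaml(path)
        cfg = cls(**data)
        cfg.curvature_smoothing = tuple(cfg.curvature_smoothing)
        cfg.motion_smoothing = tuple(cfg.motion_smoothing)
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["curvature_smoothing"] = list(self.curvature_smoothing)
        d["motion_smoothing"] = list(self.motion_smoothing)
        mio.dump_yaml(path, d)

    def digest(self) -> str:
        """Short stable hash of the analysis parameters.

        Input/output locations are excluded: the digest identifies what
        was computed, not where it was read from or written to.
        """
        d = asdict(self)
        d.pop("input", None)
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
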