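"""Kymograph rendering."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .kymograph import ScalarKymograph


def plot_kymograph(kymo: ScalarKymograph, cutoff: float | None = None,
                   tracks=None, ax=None, cmap: str = "RdBu_r"):
    """Render a kymograph; the colour scale is clipped at ``cutoff``.

    The cutoff affects only the display, never the stored values.
    Optional wave tracks are overlaid as dashed black lines.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    vmax = cutoff if cutoff is not None else float(np.abs(kymo.matrix).max())
    extent = (0.0, kymo.n_frames * kymo.frame_interval / 60.0, kymo.n_points, 0.0)
    im = ax.imshow(kymo.matrix, aspect="auto", cmap=cmap,
                   vmin=-vmax, vmax=vmax, extent=extent)
    if tracks:
        for tr in tracks:
            ax.plot(tr.frames * kymo.frame_interval / 60.0,
                    tr.indices % kymo.n_points, "k--", lw=1)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("boundary index")
    label = {"curvature": "curvature (1/µm)", "motion": "motion (µm/interval)"}
    ax.figure.colorbar(im, ax=ax, label=label.get(kymo.quantity, kymo.quantity))
    return ax


def save_kymograph_png(path, kymo: ScalarKymograph, cutoff: float | None = None,
                       tracks=None) -> None:
    ax = plot_kymograph(kymo, cutoff=cutoff, tracks=tracks)
    ax.figure.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(ax.figure)
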