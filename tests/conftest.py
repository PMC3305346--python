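import numpy as np
import pytest

import morphowave as mw
from morphowave.tracking import track_series


def circle(radius=10.0, n=400, center=(0.0, 0.0), phase=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False) + phase
    return np.column_stack([center[0] + radius * np.cos(t),
                            center[1] + radius * np.sin(t)])


def fourier_blob(rng, n=400, radius=10.0, harmonics=5, rel_amp=0.06):
    """Random smooth star-shaped boundary (low-order Fourier radial modes)."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = np.full(n, radius)
    for k in range(2, 2 + harmonics):
        r += radius * rel_amp * rng.uniform(0.2, 1.0) * np.cos(
            k * t + rng.uniform(0, 2 * np.pi)) / k
    return np.column_stack([r * np.cos(t), r * np.sin(t)])


@pytest.fixture(scope="session")
def default_sim():
    """One shared simulator movie (polarised, alternating waves)."""
    spec = mw.SyntheticCellSpec(seed=11, duration=400.0, wave_speed=20.0,
                                wave_birth_rate=3.0, alternation_prob=1.0)
    movie, truth = mw.generate_boundary_movie(spec)
    return spec, movie, truth


@pytest.fixture(scope="session")
def default_series(default_sim):
    _, movie, _ = default_sim
    return track_series(movie)
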