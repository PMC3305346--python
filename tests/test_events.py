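import numpy as np
import pytest

from morphowave.events import (
    EventParams,
    EventSet,
    MeanLocationTrace,
    boundary_msd,
    event_rates,
    extract_events,
    mean_protrusion_location,
)
from morphowave.motion import MotionField


def make_field(mat, dt=4.0, spacing=0.12):
    mat = np.asarray(mat, dtype=float)
    return MotionField(values=mat, lag_s=12.0, frame_interval=dt,
                       point_spacing=np.full(mat.shape[1], spacing))


def bump(mat, i, t, amp, si=4.0, st=1.5):
    n, T = mat.shape
    ii = np.arange(n)[:, None]
    tt = np.arange(T)[None, :]
    d = (ii - i + n / 2) % n - n / 2
    mat += amp * np.exp(-0.5 * (d / si) ** 2 - 0.5 * ((tt - t) / st) ** 2)


class TestExtractEvents:
    def test_zero_field_empty(self):
        es = extract_events(make_field(np.zeros((100, 30))),
                            EventParams(threshold=0.1))
        assert len(es) == 0

    def test_programmed_extrema_recovered(self):
        mat = np.zeros((200, 60))
        pos = [(30, 10), (100, 25), (170, 45)]
        neg = [(60, 35), (140, 50)]
        for i, t in pos:
            bump(mat, i, t, +1.0)
        for i, t in neg:
            bump(mat, i, t, -1.0)
        es = extract_events(make_field(mat), EventParams(threshold=0.5))
        prot = es.of_type("protrusion")
        retr = es.of_type("retraction")
        assert sorted(zip(prot.boundary_index, prot.frame)) == sorted(pos)
        assert sorted(zip(retr.boundary_index, retr.frame)) == sorted(neg)
        assert (prot.magnitude > 0).all() and (retr.magnitude < 0).all()

    def test_negated_field_swaps_types_exactly(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(0, 0.2, size=(150, 40))
        for k in range(6):
            bump(mat, rng.integers(0, 150), rng.integers(5, 35),
                 rng.choice([-1.5, 1.5]))
        p = EventParams(threshold=0.6)
        a = extract_events(make_field(mat), p).events
        b = extract_events(make_field(-mat), p).events
        swap = {"protrusion": "retraction", "retraction": "protrusion"}
        assert len(a) == len(b)
        merged = a.merge(b, on=["frame", "boundary_index"], suffixes=("_a", "_b"))
        assert len(merged) == len(a)
        assert (merged["type_b"] == merged["type_a"].map(swap)).all()
        assert np.allclose(merged["magnitude_b"], -merged["magnitude_a"])

    def test_steady_plateau_produces_no_events(self):
        mat = np.zeros((100, 30))
        mat[40:60, :] = 1.0  # front band moving steadily: constant in time
        es = extract_events(make_field(mat), EventParams(threshold=0.1))
        assert len(es) == 0


class TestEventRates:
    def _events(self, n_prot, duration_min):
        import pandas as pd
        df = pd.DataFrame({"frame": np.arange(n_prot), "boundary_index": 0,
                           "magnitude": 1.0, "type": "protrusion"})
        return EventSet(events=df, duration_min=duration_min, n_points=400)

    def test_simple_rate(self):
        out = event_rates(self._events(29, 10.0))
        assert out["protrusion_rate_per_min"] == pytest.approx(2.9)

    def test_empty_zero(self):
        out = event_rates(self._events(0, 10.0))
        assert out["protrusion_rate_per_min"] == 0.0

    def test_mean_and_sem_across_movies(self):
        out = event_rates([self._events(20, 10.0), self._events(40, 10.0)])
        assert out["protrusion_rate_per_min"] == pytest.approx(3.0)
        assert out["protrusion_rate_sem"] == pytest.approx(1.0)


class TestMeanLocation:
    def test_single_bump_centered(self):
        mat = np.zeros((400, 5))
        bump(mat, 120, 2, 1.0, st=100.0)
        trace = mean_protrusion_location(make_field(mat))
        assert trace.defined_mask.all()
        assert np.allclose(trace.index_location, 120.0, atol=0.01)

    def test_two_bumps_short_arc_mean(self):
        mat = np.zeros((400, 3))
        bump(mat, 100, 1, 1.0, st=100.0)
        bump(mat, 140, 1, 1.0, st=100.0)
        trace = mean_protrusion_location(make_field(mat))
        assert np.allclose(trace.index_location, 120.0, atol=0.05)

    def test_antipodal_bumps_undefined(self):
        mat = np.zeros((400, 3))
        bump(mat, 0, 1, 1.0, st=100.0)
        bump(mat, 200, 1, 1.0, st=100.0)
        trace = mean_protrusion_location(make_field(mat))
        assert not trace.defined_mask.any()

    def test_below_threshold_undefined(self):
        mat = np.full((400, 4), 0.05)
        trace = mean_protrusion_location(make_field(mat), threshold=0.1)
        assert not trace.defined_mask.any()


def make_trace(index_location, n=400, spacing=0.12, dt=4.0, defined=None):
    loc = np.asarray(index_location, dtype=float)
    if defined is None:
        defined = ~np.isnan(loc)
    return MeanLocationTrace(index_location=loc, defined_mask=defined,
                             n_points=n, point_spacing=np.full(len(loc), spacing),
                             frame_interval=dt)


class TestBoundaryMSD:
    def test_constant_speed_is_ballistic(self):
        # 4.2 indices/frame forever (wraps around the boundary)
        loc = (np.arange(150) * 4.2) % 400
        msd = boundary_msd(make_trace(loc))
        assert msd.slope_short == pytest.approx(2.0, abs=0.02)
        v = 4.2 * 0.12 / 4.0 * 60  # µm/min
        k = np.argmin(np.abs(msd.lags_s - 8.0))
        assert np.sqrt(msd.msd_um2[k]) / msd.lags_s[k] * 60 == pytest.approx(v, rel=1e-6)

    def test_stationary_msd_zero(self):
        msd = boundary_msd(make_trace(np.full(100, 37.0)))
        assert np.allclose(msd.msd_um2, 0.0)

    def test_bounded_oscillation_plateaus(self):
        """Caged motion: long-lag MSD ≈ 2·Var, local slope -> 0."""
        rng = np.random.default_rng(0)
        x = np.empty(1000)
        x[0] = 0.0
        for t in range(1, 1000):  # OU walk confined to ±10 indices
            x[t] = np.clip(0.8 * x[t - 1] + rng.normal(0, 2.4), -10, 10)
        msd = boundary_msd(make_trace(200 + x, spacing=0.12),
                           long_lag_min_s=120.0)
        assert msd.slope_long <= 0.1
        var = np.var(x * 0.12)
        sel = msd.lags_s >= 120
        assert np.mean(msd.msd_um2[sel]) == pytest.approx(2 * var, rel=0.2)
        assert msd.crossover_s <= 40.0

    def test_gaps_break_accumulation(self):
        loc = (np.arange(100) * 3.0) % 400
        loc[40:45] = np.nan
        msd = boundary_msd(make_trace(loc))
        assert msd.slope_short == pytest.approx(2.0, abs=0.02)

    def test_cyclic_relabeling_invariance(self):
        loc = (np.arange(120) * 2.5) % 400
        m1 = boundary_msd(make_trace(loc))
        m2 = boundary_msd(make_trace((loc + 157) % 400))
        assert np.allclose(m1.msd_um2, m2.msd_um2)

    def test_all_undefined_raises(self):
        with pytest.raises(ValueError):
            boundary_msd(make_trace(np.full(50, np.nan)))


def test_simulator_event_rate_and_min_speed(default_sim, default_series):
    """Closure: programmed birth rate recovered; MSD speed bound holds."""
    import morphowave as mw
    spec, _, truth = default_sim
    field = mw.local_motion(default_series)
    es = extract_events(field, EventParams(space_halfwidth=15))
    # waves at 20 µm/min travel ~10 indices/frame, so the event
    # neighbourhood spans the crest travel; one event per bump birth
    observed = es.rate("protrusion")
    expected = (truth.bumps.birth_s < field.n_frames * 4.0).sum() / field.duration_min
    assert observed == pytest.approx(expected, rel=0.15)
    trace = mean_protrusion_location(field)
    msd = boundary_msd(trace)
    assert msd.min_speed_um_min <= spec.wave_speed
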