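"""Kinematics: MSD estimator, displacement, drift subtraction, windowing."""

from __future__ import annotations

import math

import numpy as np
import pytest

from placodetrack import (
    DriftSeries,
    WalkConfig,
    drift_series,
    msd,
    orientation_angle,
    simulate_walks,
    subtract_drift,
    total_displacement,
    windowed_summaries,
)
from placodetrack.kinematics import UndefinedAngleError, fit_msd_slope
from placodetrack.tracks_io import EmptyInputError, TimedTrack, TrackSet

from conftest import make_track, make_trackset, msd_bruteforce, random_trackset


# --- MSD --------------------------------------------------------------------


def test_msd_of_ballistic_track_is_v2_tau2():
    ts = make_trackset([[[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]], dt=1.0)
    c = msd(ts, max_lag_fraction=1.0)
    np.testing.assert_allclose(c.lags, [1, 2, 3])
    np.testing.assert_allclose(c.msd, [1, 4, 9])


def test_msd_of_stationary_track_is_zero():
    ts = make_trackset([np.zeros((6, 3))], dt=10.0)
    c = msd(ts, max_lag_fraction=1.0)
    np.testing.assert_allclose(c.msd, 0.0)


def test_msd_pure_drift_exact_at_all_lags(rng):
    v = np.array([0.3, -0.2, 0.1])
    dt = 10.0
    t = np.arange(30) * dt
    ts = TrackSet(
        tracks=(TimedTrack(track_id="d", cohort="op_cell", t=t, xyz=np.outer(t, v)),),
        dt_nominal=dt,
    )
    c = msd(ts, max_lag_fraction=1.0)
    np.testing.assert_allclose(c.msd, (v @ v) * c.lags**2, rtol=1e-12)


def test_msd_matches_bruteforce_oracle_on_random_tracksets(rng):
    """Vectorised estimator == naive double-loop oracle, including gapped tracks."""
    for _ in range(25):
        ts = random_trackset(rng)
        c = msd(ts, max_lag_fraction=0.5)
        oracle = msd_bruteforce(ts, max_lag_fraction=0.5)
        assert set(np.round(c.lags, 6)) == set(np.round(list(oracle), 6))
        for lag, value, n_pairs in zip(c.lags, c.msd, c.n_pairs):
            exp_val, exp_n = oracle[lag]
            assert value == pytest.approx(exp_val, rel=1e-9)
            assert n_pairs == exp_n


def test_msd_gap_pairs_are_skipped_not_interpolated():
    # frames 0,1,2,4: lag-1 pairs exist only where consecutive frames present
    t = np.array([0.0, 10.0, 20.0, 40.0])
    xyz = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [8, 0, 0]], float)
    ts = TrackSet(
        tracks=(TimedTrack(track_id="g", cohort="op_cell", t=t, xyz=xyz),),
        dt_nominal=10.0,
    )
    c = msd(ts, max_lag_fraction=1.0)
    by_lag = dict(zip(c.lags, c.msd))
    assert by_lag[10.0] == pytest.approx(1.0)  # pairs (0,1),(1,2); (2,4) skipped
    assert dict(zip(c.lags, c.n_pairs))[10.0] == 2


def test_msd_brownian_slope_recovers_6d():
    d_true = 0.05
    ts = simulate_walks(
        WalkConfig(n_tracks=200, n_frames=60, dt=10.0, diffusion=d_true, seed=42)
    )
    slope = fit_msd_slope(msd(ts), n_lags=10)
    assert slope == pytest.approx(6 * d_true, rel=0.10)


def test_msd_empty_selection_errors():
    ts = make_trackset([np.zeros((3, 3))], cohort="brain_cell")
    with pytest.raises(EmptyInputError):
        msd(ts, cohort="growth_cone")


# --- total displacement -----------------------------------------------------


def test_total_displacement_endpoint_differences():
    tr = make_track([[0, 0, 0], [6, -1, 2], [12, -3, 5]], dt=10.0)
    assert total_displacement(tr, "ml", 0, 20) == pytest.approx(12)
    assert total_displacement(tr, "dv", 0, 20) == pytest.approx(-3)
    assert total_displacement(tr, "ap", 0, 20) == pytest.approx(5)


def test_total_displacement_rejects_reversed_window():
    tr = make_track([[0, 0, 0], [1, 1, 1]], dt=10.0)
    with pytest.raises(ValueError, match="greater than"):
        total_displacement(tr, "ml", 10, 0)


def test_total_displacement_nearest_sample_rule():
    # samples at t=0..600 step 10; query t0=17 snaps to t=20, t1=600 to itself
    t = np.arange(0, 601, 10, dtype=float)
    xyz = np.column_stack([t.copy(), np.zeros_like(t), np.zeros_like(t)])
    tr = TimedTrack(track_id="n", cohort="op_cell", t=t, xyz=xyz)
    assert total_displacement(tr, "ml", 17, 600) == pytest.approx(600 - 20)


def test_total_displacement_outside_span_errors():
    tr = make_track([[0, 0, 0], [1, 1, 1]], dt=10.0)
    with pytest.raises(ValueError, match="outside track span"):
        total_displacement(tr, "ml", 0, 50)


# --- drift series and subtraction ------------------------------------------


def test_drift_series_mean_of_identical_steps():
    step = np.array([1.0, -2.0, 0.0])
    xyz = np.outer(np.arange(5), step)
    ts = make_trackset([xyz + i for i in range(3)], dt=10.0)
    ds = drift_series(ts, "op_cell")
    np.testing.assert_allclose(ds.mean_step, np.tile(step, (4, 1)))
    np.testing.assert_array_equal(ds.n_cells, 3)


def test_drift_series_symmetric_steps_cancel():
    a = np.outer(np.arange(4), [1.0, 0, 0])
    b = np.outer(np.arange(4), [-1.0, 0, 0])
    ds = drift_series(make_trackset([a, b]), "op_cell")
    np.testing.assert_allclose(ds.mean_step, 0.0)


def test_drift_series_absent_track_reduces_count():
    full = make_track(np.outer(np.arange(6), [1.0, 0, 0]), track_id="a")
    # second reference track misses frame 3 (t=30)
    t = np.array([0.0, 10.0, 20.0, 40.0, 50.0])
    partial = TimedTrack(
        track_id="b", cohort="op_cell", t=t,
        xyz=np.outer(t / 10.0, [1.0, 0, 0]),
    )
    ts = TrackSet(tracks=(full, partial), dt_nominal=10.0)
    ds = drift_series(ts, "op_cell")
    counts = dict(zip(ds.frames, ds.n_cells))
    assert counts[20.0] == 1 and counts[30.0] == 1  # steps touching the gap
    assert counts[0.0] == 2


def test_drift_series_empty_reference_errors():
    ts = make_trackset([np.zeros((3, 3))], cohort="brain_cell")
    with pytest.raises(EmptyInputError):
        drift_series(ts, "op_cell")


def test_subtract_drift_componentwise():
    gc = make_track(np.outer(np.arange(5), [1.0, 1.0, 0.0]), cohort="growth_cone")
    drift = DriftSeries(
        frames=np.arange(4) * 10.0,
        mean_step=np.tile([1.0, 0.0, 0.0], (4, 1)),
        n_cells=np.ones(4, int),
        dt=10.0,
    )
    corr = subtract_drift(gc, drift)
    np.testing.assert_allclose(np.diff(corr.xyz, axis=0), np.tile([0, 1, 0], (4, 1)))
    np.testing.assert_allclose(corr.xyz[0], gc.xyz[0])  # anchored at first sample


def test_subtract_own_drift_makes_track_stationary():
    xyz = np.outer(np.arange(6), [2.0, -1.0, 0.5])
    ts = make_trackset([xyz, xyz + 3.0])
    ds = drift_series(ts, "op_cell")
    corr = subtract_drift(ts.tracks[0], ds)
    np.testing.assert_allclose(corr.xyz, np.tile(corr.xyz[0], (6, 1)), atol=1e-12)


def test_subtract_zero_drift_is_identity():
    tr = make_track(np.cumsum(np.ones((5, 3)), axis=0))
    drift = DriftSeries.zero(np.arange(4) * 10.0, dt=10.0)
    corr = subtract_drift(tr, drift)
    np.testing.assert_allclose(corr.xyz, tr.xyz)


def test_subtract_drift_missing_frames_listed():
    tr = make_track(np.zeros((5, 3)) + np.arange(5)[:, None])
    short = DriftSeries.zero(np.arange(2) * 10.0, dt=10.0)
    with pytest.raises(ValueError, match="missing frames"):
        subtract_drift(tr, short)


def test_cohort_mean_net_displacement_zero_after_own_drift_subtraction(rng):
    ts = simulate_walks(WalkConfig(n_tracks=15, n_frames=30, diffusion=0.05, drift=(0.2, -0.1, 0.0), seed=7))
    ds = drift_series(ts, "op_cell")
    nets = [
        subtract_drift(tr, ds).xyz[-1] - tr.xyz[0] for tr in ts.tracks
    ]
    np.testing.assert_allclose(np.mean(nets, axis=0), 0.0, atol=1e-9)


# --- windows, persistence, orientation --------------------------------------


def test_four_windows_of_200_from_200_over_1000_min_movie():
    ts = simulate_walks(WalkConfig(n_tracks=2, n_frames=101, dt=10.0, diffusion=0.01, seed=3))
    sums = windowed_summaries(ts, t_start=200.0, window_len=200.0, n_windows=4)
    windows = sorted({s.window for s in sums})
    assert windows == [(200, 400), (400, 600), (600, 800), (800, 1000)]


def test_windows_beyond_movie_span_error():
    ts = simulate_walks(WalkConfig(n_tracks=1, n_frames=11, dt=10.0, seed=0))
    with pytest.raises(ValueError, match="exceed"):
        windowed_summaries(ts, t_start=0.0, window_len=60.0, n_windows=3)


def test_persistence_straight_track_is_one():
    ts = make_trackset([[[0, 0, 0], [1.5, 2, 0], [3, 4, 0]]], dt=10.0)
    (s,) = windowed_summaries(ts, 0.0, 20.0, 1)
    assert s.persistence == pytest.approx(1.0)
    assert s.path_length == pytest.approx(5.0)


def test_persistence_out_and_back_is_zero():
    ts = make_trackset([[[0, 0, 0], [1, 0, 0], [0, 0, 0]]], dt=10.0)
    (s,) = windowed_summaries(ts, 0.0, 20.0, 1)
    assert s.persistence == pytest.approx(0.0)


def test_persistence_l_track():
    ts = make_trackset([[[0, 0, 0], [1, 0, 0], [1, 1, 0]]], dt=10.0)
    (s,) = windowed_summaries(ts, 0.0, 20.0, 1)
    assert s.persistence == pytest.approx(math.sqrt(2) / 2)


def test_persistence_bounded_on_random_tracks(rng):
    ts = random_trackset(rng, max_tracks=10, max_frames=20)
    span = ts.time_span()
    sums = windowed_summaries(ts, 0.0, span[1], 1)
    for s in sums:
        assert 0.0 <= s.persistence <= 1.0
        assert s.path_length >= np.linalg.norm(s.net_displacement) - 1e-9


def test_mean_speed_uses_in_window_path_and_time():
    # 2 steps of length 5 µm each over 20 min → 0.5 µm/min
    ts = make_trackset([[[0, 0, 0], [3, 4, 0], [6, 8, 0]]], dt=10.0)
    (s,) = windowed_summaries(ts, 0.0, 20.0, 1)
    assert s.mean_speed == pytest.approx(0.5)


@pytest.mark.parametrize(
    "net, expected_deg",
    [((0, 5), 0.0), ((5, 0), 90.0), ((5, 5), 45.0), ((-5, 0), -90.0), ((0, -5), 180.0)],
)
def test_orientation_angle_ml_dv_convention(net, expected_deg):
    tr = make_track([[0, 0, 0], [net[0], net[1], 0]], dt=10.0)
    assert orientation_angle(tr, "ml_dv") == pytest.approx(expected_deg)


def test_orientation_angle_ml_ap_uses_ap_reference():
    tr = make_track([[0, 0, 0], [0, 3, 5]], dt=10.0)
    assert orientation_angle(tr, "ml_ap") == pytest.approx(0.0)


def test_orientation_angle_zero_net_displacement_raises():
    tr = make_track([[0, 0, 0], [1, 1, 0], [0, 0, 0]], dt=10.0)
    with pytest.raises(UndefinedAngleError):
        orientation_angle(tr, "ml_dv")
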