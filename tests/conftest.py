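"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from placodetrack import TimedTrack, TrackSet


def make_track(
    xyz, dt=10.0, track_id="t0", cohort="op_cell", t=None
) -> TimedTrack:
    xyz = np.asarray(xyz, dtype=float)
    if t is None:
        t = np.arange(xyz.shape[0], dtype=float) * dt
    return TimedTrack(track_id=track_id, cohort=cohort, t=np.asarray(t, float), xyz=xyz)


def make_trackset(list_of_xyz, dt=10.0, cohort="op_cell") -> TrackSet:
    tracks = [
        make_track(xyz, dt=dt, track_id=f"t{i}", cohort=cohort)
        for i, xyz in enumerate(list_of_xyz)
    ]
    return TrackSet(tracks=tuple(tracks), dt_nominal=dt)


def random_trackset(
    rng: np.random.Generator,
    max_tracks: int = 20,
    max_frames: int = 50,
    dt: float = 10.0,
    gap_prob: float = 0.15,
) -> TrackSet:
    """Random valid TrackSet with occasional missing frames (gaps)."""
    n_tracks = int(rng.integers(1, max_tracks + 1))
    tracks = []
    for i in range(n_tracks):
        n_frames = int(rng.integers(2, max_frames + 1))
        frames = np.arange(n_frames)
        if n_frames > 4 and rng.random() < gap_prob:
            keep = np.sort(
                rng.choice(frames[1:-1], size=n_frames - 3, replace=False)
            )
            frames = np.concatenate([[0], keep, [n_frames - 1]])
        t = frames.astype(float) * dt
        xyz = rng.normal(0, 10, size=(frames.size, 3))
        tracks.append(
            TimedTrack(track_id=f"r{i}", cohort="op_cell", t=t, xyz=xyz)
        )
    return TrackSet(tracks=tuple(tracks), dt_nominal=dt)


def msd_bruteforce(ts: TrackSet, max_lag_fraction: float = 0.5):
    """Independent double-loop time-averaged MSD; returns {lag_min: (msd, n_pairs)}.

    Deliberately naive: per track, iterate over every ordered sample pair and
    bucket by exact time difference; then average per-track means per lag.
    """
    dt = ts.dt_nominal
    per_track: dict[float, list[float]] = {}
    pair_count: dict[float, int] = {}
    for tr in ts.tracks:
        if tr.n_samples < 2:
            continue
        max_lag = max_lag_fraction * (tr.t[-1] - tr.t[0])
        sums: dict[float, list[float]] = {}
        for i in range(tr.n_samples):
            for j in range(i + 1, tr.n_samples):
                lag = tr.t[j] - tr.t[i]
                k = round(lag / dt)
                if abs(k * dt - lag) > 1e-6 * dt:
                    continue  # pair spans a gap at a non-integer lag (cannot occur)
                if lag > max_lag + 1e-9:
                    continue
                d = tr.xyz[j] - tr.xyz[i]
                sums.setdefault(lag, []).append(float(d @ d))
        for lag, vals in sums.items():
            per_track.setdefault(lag, []).append(float(np.mean(vals)))
            pair_count[lag] = pair_count.get(lag, 0) + len(vals)
    return {
        lag: (float(np.mean(v)), pair_count[lag]) for lag, v in per_track.items()
    }


def connected_components_bruteforce(points: np.ndarray, link_dist: float):
    """Label points by exhaustive transitive closure of the <=link_dist relation."""
    n = points.shape[0]
    labels = list(range(n))
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(n):
                if np.linalg.norm(points[i] - points[j]) <= link_dist:
                    lo = min(labels[i], labels[j])
                    if labels[i] != lo or labels[j] != lo:
                        labels[i] = labels[j] = lo
                        changed = True
    return np.asarray(labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
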