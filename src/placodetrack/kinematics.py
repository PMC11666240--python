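"""Per-track and ensemble kinematics: MSD, displacement, speed, persistence,
tissue-drift subtraction, windowing and orientation angles.

The mean squared displacement is time-averaged over all overlapping sample
pairs within each track, MSD_i(τ) = ⟨|r(t+τ) − r(t)|²⟩_t, and then averaged
across tracks with equal weight per track. Pairs spanning a recorded gap are
excluded rather than interpolated, which would bias short-lag estimates.
For pure drift at velocity v the curve is |v|²τ²; for 3D diffusion with
coefficient D its slope is 6D.

Tissue drift (e.g. the forebrain flexure) is represented as the frame-wise
mean step of a reference cohort and removed from a track by subtracting the
accumulated reference motion, anchored at the track's first sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tracks_io import EmptyInputError, TimedTrack, TrackSet

__all__ = [
    "MsdCurve",
    "DriftSeries",
    "KinematicSummary",
    "UndefinedAngleError",
    "msd",
    "total_displacement",
    "drift_series",
    "subtract_drift",
    "windowed_summaries",
    "orientation_angle",
    "fit_msd_slope",
]

logger = logging.getLogger(__name__)

_AXIS_COLUMN = {"ml": 0, "dv": 1, "ap": 2}


class UndefinedAngleError(ValueError):
    """Raised when a track's net in-plane displacement is zero."""


@dataclass(frozen=True)
class MsdCurve:
    """Lag-indexed ensemble MSD with per-lag pair counts."""

    lags: np.ndarray  # minutes, strictly increasing multiples of dt
    msd: np.ndarray  # µm²
    n_pairs: np.ndarray  # total displacement pairs per lag
    n_tracks: int

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        vals = np.asarray(self.msd, dtype=float)
        pairs = np.asarray(self.n_pairs, dtype=np.int64)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "msd", vals)
        object.__setattr__(self, "n_pairs", pairs)
        if not (lags.size == vals.size == pairs.size):
            raise ValueError("lags, msd, n_pairs must be parallel")
        if lags.size and np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(vals < 0):
            raise ValueError("msd must be non-negative")
        if np.any(pairs <= 0):
            raise ValueError("every reported lag needs n_pairs > 0")


@dataclass(frozen=True)
class DriftSeries:
    """Frame-wise mean displacement of a reference cohort.

    ``mean_step[k]`` is the mean 3D step of the reference cohort from
    ``frames[k]`` to ``frames[k] + dt``; ``n_cells[k]`` counts the tracks
    present at both ends of that step.
    """

    frames: np.ndarray  # start time (min) of each step
    mean_step: np.ndarray  # (n, 3) µm
    n_cells: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        step = np.asarray(self.mean_step, dtype=float)
        n = np.asarray(self.n_cells, dtype=np.int64)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "mean_step", step)
        object.__setattr__(self, "n_cells", n)
        if step.shape != (frames.size, 3) or n.size != frames.size:
            raise ValueError("frames, mean_step, n_cells must be parallel")

    @classmethod
    def zero(cls, frames: np.ndarray, dt: float) -> "DriftSeries":
        frames = np.asarray(frames, dtype=float)
        return cls(
            frames=frames,
            mean_step=np.zeros((frames.size, 3)),
            n_cells=np.ones(frames.size, dtype=np.int64),
            dt=dt,
        )

    def cumulative_at(self, times: np.ndarray, anchor: float) -> np.ndarray:
        """Accumulated drift from `anchor` up to (not including) each time."""
        times = np.asarray(times, dtype=float)
        out = np.zeros((times.size, 3))
        for i, t in enumerate(times):
            sel = (self.frames >= anchor - 1e-9) & (self.frames < t - 1e-9)
            out[i] = self.mean_step[sel].sum(axis=0)
        return out


@dataclass(frozen=True)
class KinematicSummary:
    """Speed/persistence summary of one track inside one time window."""

    track_id: str
    window: tuple[float, float]
    mean_speed: float  # µm/min
    persistence: float  # |net| / path length, in [0, 1]
    net_displacement: np.ndarray  # (3,) µm
    path_length: float  # µm
    orientation_deg: float  # (−180, 180], NaN if net in-plane displacement is 0
    cohort: str = ""


def _frame_positions(track: TimedTrack, dt: float) -> dict[int, np.ndarray]:
    f = track.frame_indices(dt)
    return {int(k): track.xyz[i] for i, k in enumerate(f)}


def msd(
    tracks: TrackSet,
    cohort: str | Sequence[str] | None = None,
    max_lag_fraction: float = 0.5,
) -> MsdCurve:
    """Ensemble time-averaged 3D MSD of the selected cohort.

    For each track, lags τ = k·dt run up to ``max_lag_fraction`` of that
    track's duration; MSD_i(τ) averages |r(t+τ) − r(t)|² over all sample
    pairs separated by τ (pairs spanning gaps are skipped). The ensemble
    curve is the unweighted mean of MSD_i over tracks contributing at that
    lag; ``n_pairs`` reports the total pair count per lag.
    """
    if not (0 < max_lag_fraction <= 1):
        raise ValueError("max_lag_fraction must be in (0, 1]")
    selected = [tr for tr in tracks.select(cohort) if tr.n_samples >= 2]
    if not selected:
        raise EmptyInputError("no track with >= 2 samples matches the cohort filter")
    dt = tracks.dt_nominal

    per_track_msd: dict[int, list[float]] = {}
    pair_counts: dict[int, int] = {}
    for tr in selected:
        f = tr.frame_indices(dt)
        f0 = f - f[0]
        n_frames = int(f0[-1]) + 1
        pos = np.full((n_frames, 3), np.nan)
        pos[f0] = tr.xyz
        k_max = int(math.floor(max_lag_fraction * tr.duration / dt + 1e-9))
        for k in range(1, min(k_max, n_frames - 1) + 1):
            d = pos[k:] - pos[:-k]
            sq = np.einsum("ij,ij->i", d, d)
            valid = ~np.isnan(sq)
            if not np.any(valid):
                continue
            per_track_msd.setdefault(k, []).append(float(sq[valid].mean()))
            pair_counts[k] = pair_counts.get(k, 0) + int(valid.sum())

    requested = range(1, max(per_track_msd, default=0) + 1)
    skipped = [k for k in requested if k not in per_track_msd]
    if skipped:
        logger.warning("lags %s omitted: all pairs span gaps", skipped)
    ks = np.array(sorted(per_track_msd), dtype=np.int64)
    return MsdCurve(
        lags=ks * dt,
        msd=np.array([np.mean(per_track_msd[k]) for k in ks]),
        n_pairs=np.array([pair_counts[k] for k in ks], dtype=np.int64),
        n_tracks=len(selected),
    )


def fit_msd_slope(curve: MsdCurve, n_lags: int = 10) -> float:
    """Least-squares slope of MSD(τ) vs τ through the origin-free line,
    over the first `n_lags` lags (µm²/min)."""
    k = min(n_lags, curve.lags.size)
    if k < 2:
        raise ValueError("need >= 2 lags to fit a slope")
    slope, _ = np.polyfit(curve.lags[:k], curve.msd[:k], 1)
    return float(slope)


def total_displacement(
    track: TimedTrack, axis: str, t0: float, t1: float
) -> float:
    """Signed displacement along one axis between the samples nearest t0, t1.

    The nearest-sample rule is used at both ends; no extrapolation, so the
    query window must lie within the track's time span.
    """
    if axis not in _AXIS_COLUMN:
        raise ValueError(f"axis must be one of {sorted(_AXIS_COLUMN)}")
    if t1 <= t0:
        raise ValueError("t1 must be greater than t0")
    if t0 < track.t[0] - 1e-9 or t1 > track.t[-1] + 1e-9:
        raise ValueError(
            f"window [{t0}, {t1}] outside track span "
            f"[{track.t[0]}, {track.t[-1]}]"
        )
    i0 = int(np.argmin(np.abs(track.t - t0)))
    i1 = int(np.argmin(np.abs(track.t - t1)))
    col = _AXIS_COLUMN[axis]
    return float(track.xyz[i1, col] - track.xyz[i0, col])


def drift_series(
    tracks: TrackSet, reference_cohort: str | Sequence[str] = "op_cell"
) -> DriftSeries:
    """Frame-wise mean movement of a reference cohort (the tissue drift).

    Frames inside the reference cohort's span with no track present at both
    ends of the step carry a zero step (with a warning) rather than an
    interpolated one.
    """
    ref = tracks.select(reference_cohort)
    if not ref:
        raise EmptyInputError(f"reference cohort {reference_cohort!r} is empty")
    dt = tracks.dt_nominal
    maps = [_frame_positions(tr, dt) for tr in ref]
    lo = min(min(m) for m in maps)
    hi = max(max(m) for m in maps)
    frames = np.arange(lo, hi, dtype=np.int64)
    mean_step = np.zeros((frames.size, 3))
    n_cells = np.zeros(frames.size, dtype=np.int64)
    for idx, k in enumerate(frames):
        steps = [
            m[k + 1] - m[k] for m in maps if int(k) in m and int(k) + 1 in m
        ]
        if steps:
            mean_step[idx] = np.mean(steps, axis=0)
            n_cells[idx] = len(steps)
        else:
            logger.warning(
                "no reference cell spans frame %d -> %d; zero drift step used",
                k,
                k + 1,
            )
    return DriftSeries(
        frames=frames.astype(float) * dt, mean_step=mean_step, n_cells=n_cells, dt=dt
    )


def subtract_drift(track: TimedTrack, drift: DriftSeries) -> TimedTrack:
    """Remove accumulated reference-cohort motion from a track.

    The corrected positions are r'(t_n) = r(t_n) − Σ_{m<n} mean_step[m],
    anchored so the first sample is unchanged. The drift series must cover
    every frame interval inside the track's span.
    """
    t0, t1 = float(track.t[0]), float(track.t[-1])
    needed = np.arange(
        round(t0 / drift.dt), round(t1 / drift.dt), dtype=np.int64
    ) * drift.dt
    have = {round(f / drift.dt) for f in drift.frames}
    missing = [float(f) for f in needed if round(f / drift.dt) not in have]
    if missing:
        raise ValueError(
            f"drift series does not cover track {track.track_id!r}; "
            f"missing frames at t = {missing}"
        )
    correction = drift.cumulative_at(track.t, anchor=t0)
    return TimedTrack(
        track_id=track.track_id,
        cohort=track.cohort,
        t=track.t.copy(),
        xyz=track.xyz - correction,
        embryo_id=track.embryo_id,
        side=track.side,
    )


def _net_angle_deg(net: np.ndarray, plane: str) -> float:
    if plane == "ml_dv":
        d_ml, d_ref = net[0], net[1]
    elif plane == "ml_ap":
        d_ml, d_ref = net[0], net[2]
    else:
        raise ValueError("plane must be 'ml_dv' or 'ml_ap'")
    if d_ml == 0.0 and d_ref == 0.0:
        raise UndefinedAngleError("zero net in-plane displacement")
    ang = math.degrees(math.atan2(d_ml, d_ref))
    if ang <= -180.0:
        ang += 360.0
    return ang


def orientation_angle(
    track: TimedTrack,
    plane: str = "ml_dv",
    window: tuple[float, float] | None = None,
) -> float:
    """Angle of the windowed net displacement against the reference axis.

    In the ML–DV plane the angle is atan2(Δml, Δdv) in degrees within
    (−180, 180]: pure dorsal motion is 0°, pure lateral (+ML) is +90°. The
    ML–AP variant uses AP as the reference axis. Raises
    :class:`UndefinedAngleError` when the net in-plane displacement is zero
    (such tracks are excluded from circular samples and counted in the log).
    """
    if window is None:
        i0, i1 = 0, track.n_samples - 1
    else:
        t0, t1 = window
        if t1 <= t0:
            raise ValueError("window end must exceed window start")
        i0 = int(np.argmin(np.abs(track.t - t0)))
        i1 = int(np.argmin(np.abs(track.t - t1)))
    net = track.xyz[i1] - track.xyz[i0]
    return _net_angle_deg(net, plane)


def windowed_summaries(
    tracks: TrackSet,
    t_start: float,
    window_len: float,
    n_windows: int,
    drift: DriftSeries | None = None,
    cohort: str | Sequence[str] | None = None,
    plane: str = "ml_dv",
) -> list[KinematicSummary]:
    """Per-track speed/persistence summaries over consecutive time windows.

    Windows are the closed intervals [t_start + i·w, t_start + (i+1)·w] for
    i = 0..n_windows−1; a sample on a shared boundary belongs to both
    adjacent windows. A track contributes to a window only if it has at
    least two samples inside it. With `drift` given, summaries are computed
    on drift-corrected positions.

    mean_speed is path length divided by the elapsed time between the first
    and last in-window samples; persistence is |net displacement| / path
    length (defined as 0 for a zero path).
    """
    if t_start < 0:
        raise ValueError("t_start must be >= 0")
    if window_len <= tracks.dt_nominal:
        raise ValueError("window_len must exceed the frame interval")
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    _, t_max = tracks.time_span()
    if t_start + n_windows * window_len > t_max + 1e-9:
        raise ValueError(
            f"{n_windows} windows of {window_len} min from t={t_start} exceed "
            f"the movie span (ends at {t_max} min)"
        )
    selected = tracks.select(cohort)
    out: list[KinematicSummary] = []
    n_undefined = 0
    for i in range(n_windows):
        w0 = t_start + i * window_len
        w1 = w0 + window_len
        for tr in selected:
            if drift is not None:
                tr_use = subtract_drift(tr, drift)
            else:
                tr_use = tr
            inside = (tr_use.t >= w0 - 1e-9) & (tr_use.t <= w1 + 1e-9)
            if inside.sum() < 2:
                continue
            t_in = tr_use.t[inside]
            p_in = tr_use.xyz[inside]
            steps = np.diff(p_in, axis=0)
            path = float(np.sqrt((steps**2).sum(axis=1)).sum())
            net = p_in[-1] - p_in[0]
            elapsed = float(t_in[-1] - t_in[0])
            persistence = float(np.linalg.norm(net) / path) if path > 0 else 0.0
            try:
                ang = _net_angle_deg(net, plane)
            except UndefinedAngleError:
                ang = math.nan
                n_undefined += 1
            out.append(
                KinematicSummary(
                    track_id=tr.track_id,
                    window=(w0, w1),
                    mean_speed=path / elapsed if elapsed > 0 else 0.0,
                    persistence=min(persistence, 1.0),
                    net_displacement=net,
                    path_length=path,
                    orientation_deg=ang,
                    cohort=tr.cohort,
                )
            )
    if n_undefined:
        logger.info(
            "%d track-window(s) had zero net in-plane displacement "
            "(orientation undefined)",
            n_undefined,
        )
    return out
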