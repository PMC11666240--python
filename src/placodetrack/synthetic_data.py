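"""Seeded generators for synthetic tracking, boundary and interface data.

The track generator produces drift + diffusion + persistence random walks
mimicking the live-imaging regimes the analyses target: frames every 10
minutes over 600–1000 minutes, cohorts of placode and brain cells sharing a
tissue-wide "flexure" drift, and growth cones whose recorded motion is an
intrinsic walk plus the accumulated motion of the placode cell bodies.

Persistence is implemented as a lag-1 autocorrelation on the step noise
(a discrete Ornstein–Uhlenbeck-like process); the generator parameter is a
step-direction correlation and is distinct from the measured persistence
statistic (net displacement over path length). Each per-axis step has
variance 2·D·dt in the stationary regime.

All generators are pure functions of their configuration and seed: the same
inputs give bit-identical outputs, and no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tracks_io import (
    BoundaryPolyline,
    InterfaceRegion,
    LabeledPointCloud,
    TimedTrack,
    TrackSet,
)
from .kinematics import DriftSeries, drift_series

__all__ = [
    "WalkConfig",
    "BoundaryConfig",
    "simulate_cohorts",
    "simulate_walks",
    "simulate_growth_cones",
    "make_boundary",
    "make_interface",
    "make_point_cloud",
]


@dataclass(frozen=True)
class WalkConfig:
    """Parameters of one cohort of drift+diffusion+persistence random walks.

    Attributes
    ----------
    n_tracks : int
        Number of tracks in the cohort.
    n_frames : int
        Samples per track (>= 2); frames are 0, dt, 2·dt, ...
    dt : float
        Frame interval in minutes (10 in the imaging regimes emulated).
    drift : 3-vector
        Deterministic velocity in µm/min (ML, DV, AP).
    diffusion : float
        D in µm²/min; per-axis step noise variance is 2·D·dt.
    persistence_p : float
        Lag-1 correlation of step noise, in [0, 1).
    start_spread : float
        Starting positions are uniform in a cube of this half-width (µm).
    seed : int
        RNG seed; identical config+seed gives bit-identical tracks.
    """

    n_tracks: int = 20
    n_frames: int = 101  # 1000 min at dt=10
    dt: float = 10.0
    drift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    diffusion: float = 0.05
    persistence_p: float = 0.0
    start_spread: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.diffusion < 0:
            raise ValueError("diffusion must be >= 0")
        if not (0.0 <= self.persistence_p < 1.0):
            raise ValueError("persistence_p must be in [0, 1)")
        if len(self.drift) != 3:
            raise ValueError("drift must be a 3-vector")


@dataclass(frozen=True)
class BoundaryConfig:
    """Sinusoidal boundary of controlled roughness: ml(dv) = A·sin(2π·w·dv/span)."""

    dv_span: float = 100.0
    amplitude: float = 5.0
    n_waves: int = 3
    n_vertices: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertices < 2:
            raise ValueError("n_vertices must be >= 2")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.dv_span <= 0:
            raise ValueError("dv_span must be positive")


def _walk_positions(
    cfg: WalkConfig,
    rng: np.random.Generator,
    extra_step: np.ndarray | None = None,
) -> np.ndarray:
    """Positions (n_tracks, n_frames, 3) of one cohort; `extra_step` is an
    optional shared per-frame displacement (n_frames−1, 3) added to all tracks."""
    n, m = cfg.n_tracks, cfg.n_frames
    start = rng.uniform(-cfg.start_spread, cfg.start_spread, size=(n, 3))
    sigma = np.sqrt(2.0 * cfg.diffusion * cfg.dt)
    p = cfg.persistence_p
    noise = np.zeros((n, m - 1, 3))
    if sigma > 0:
        white = rng.normal(0.0, sigma, size=(n, m - 1, 3))
        noise[:, 0] = white[:, 0]
        scale = np.sqrt(1.0 - p * p)
        for k in range(1, m - 1):  # stationary AR(1): marginal std stays sigma
            noise[:, k] = p * noise[:, k - 1] + scale * white[:, k]
    steps = noise + np.asarray(cfg.drift, float) * cfg.dt
    if extra_step is not None:
        steps = steps + extra_step[None, :, :]
    pos = np.empty((n, m, 3))
    pos[:, 0] = start
    pos[:, 1:] = start[:, None, :] + np.cumsum(steps, axis=1)
    return pos


def _to_tracks(
    pos: np.ndarray, cfg: WalkConfig, cohort: str, prefix: str
) -> list[TimedTrack]:
    t = np.arange(cfg.n_frames, dtype=float) * cfg.dt
    return [
        TimedTrack(
            track_id=f"{prefix}{i:03d}",
            cohort=cohort,
            t=t.copy(),
            xyz=pos[i],
        )
        for i in range(cfg.n_tracks)
    ]


def simulate_walks(cfg: WalkConfig, cohort: str = "op_cell", prefix: str = "trk") -> TrackSet:
    """One cohort of persistent random walks as a TrackSet."""
    rng = np.random.default_rng(cfg.seed)
    pos = _walk_positions(cfg, rng)
    return TrackSet(tracks=tuple(_to_tracks(pos, cfg, cohort, prefix)), dt_nominal=cfg.dt)


def _shared_step_array(
    shared_drift, n_steps: int, dt: float
) -> np.ndarray | None:
    if shared_drift is None:
        return None
    arr = np.asarray(shared_drift, dtype=float)
    if arr.shape == (3,):
        return np.broadcast_to(arr * dt, (n_steps, 3)).copy()
    if arr.shape == (n_steps, 3):
        return arr * dt
    raise ValueError(
        "shared_drift must be a 3-vector (µm/min) or an (n_frames-1, 3) series"
    )


def simulate_cohorts(
    op_cfg: WalkConfig,
    brain_cfg: WalkConfig,
    shared_drift=None,
) -> TrackSet:
    """Placode and brain cohorts coupled by a shared tissue drift.

    `shared_drift` is a velocity (µm/min), either constant (3-vector) or a
    per-frame series of shape (n_frames−1, 3), applied identically to both
    cohorts on top of their own drift and noise — the synthetic analogue of
    the forebrain flexure displacing both tissues together.
    """
    if op_cfg.dt != brain_cfg.dt or op_cfg.n_frames != brain_cfg.n_frames:
        raise ValueError("cohorts must share dt and n_frames")
    extra = _shared_step_array(shared_drift, op_cfg.n_frames - 1, op_cfg.dt)
    rng_op = np.random.default_rng(op_cfg.seed)
    rng_brain = np.random.default_rng(brain_cfg.seed)
    pos_op = _walk_positions(op_cfg, rng_op, extra)
    pos_brain = _walk_positions(brain_cfg, rng_brain, extra)
    tracks = _to_tracks(pos_op, op_cfg, "op_cell", "op") + _to_tracks(
        pos_brain, brain_cfg, "brain_cell", "br"
    )
    return TrackSet(tracks=tuple(tracks), dt_nominal=op_cfg.dt)


def simulate_growth_cones(
    cfg: WalkConfig,
    reference: TrackSet,
    intrinsic_drift: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> TrackSet:
    """Growth cones riding on a moving reference tissue.

    Each growth-cone position is an intrinsic walk (with `intrinsic_drift`
    and the config's diffusion) plus the accumulated frame-wise mean motion
    of the reference cohort, so drift subtraction against that cohort
    recovers the intrinsic walk by construction.
    """
    if len(reference) == 0:
        raise ValueError("reference TrackSet is empty")
    ref_cohorts = {tr.cohort for tr in reference.tracks}
    drift = drift_series(reference, reference_cohort=sorted(ref_cohorts))
    n_steps = cfg.n_frames - 1
    if drift.frames.size < n_steps:
        raise ValueError(
            "reference cohort does not cover the growth-cone frame range"
        )
    cfg_int = WalkConfig(
        n_tracks=cfg.n_tracks,
        n_frames=cfg.n_frames,
        dt=cfg.dt,
        drift=tuple(intrinsic_drift),
        diffusion=cfg.diffusion,
        persistence_p=cfg.persistence_p,
        start_spread=cfg.start_spread,
        seed=cfg.seed,
    )
    rng = np.random.default_rng(cfg_int.seed)
    pos = _walk_positions(cfg_int, rng, extra_step=drift.mean_step[:n_steps])
    return TrackSet(
        tracks=tuple(_to_tracks(pos, cfg_int, "growth_cone", "gc")),
        dt_nominal=cfg.dt,
    )


def make_boundary(cfg: BoundaryConfig) -> BoundaryPolyline:
    """Sinusoidal boundary polyline sampled ventral→dorsal.

    With ``amplitude = 0`` the boundary is a straight DV segment and its
    distortion index is exactly 1.
    """
    dv = np.linspace(0.0, cfg.dv_span, cfg.n_vertices)
    ml = cfg.amplitude * np.sin(2.0 * np.pi * cfg.n_waves * dv / cfg.dv_span)
    return BoundaryPolyline(vertices=np.column_stack([ml, dv]))


def make_interface(
    gap_px: float,
    region_length_px: int = 1000,
    roughness_px: float = 0.0,
    seed: int = 0,
    px_size_nm: float = 1.0,
) -> InterfaceRegion:
    """Paired membranes at a controlled gap with bounded roughness.

    Membrane A is straight; membrane B sits at ``gap_px`` plus a seeded,
    zero-mean smooth perturbation whose magnitude never exceeds
    ``roughness_px``. Requires ``gap_px > roughness_px`` so the membranes
    cannot touch.
    """
    if roughness_px < 0:
        raise ValueError("roughness_px must be >= 0")
    if gap_px <= roughness_px:
        raise ValueError("gap must exceed roughness (membranes could touch)")
    rng = np.random.default_rng(seed)
    n_pts = max(region_length_px // 10 + 1, 2)
    x = np.linspace(0.0, float(region_length_px), n_pts)
    a = BoundaryPolyline(vertices=np.column_stack([x, np.zeros(n_pts)]))
    if roughness_px > 0:
        n_ctrl = max(region_length_px // 100 + 1, 3)
        ctrl_x = np.linspace(0.0, float(region_length_px), n_ctrl)
        ctrl = rng.uniform(-1.0, 1.0, size=n_ctrl)
        ctrl = ctrl - ctrl.mean()
        peak = np.abs(ctrl).max()
        if peak > 0:
            ctrl = ctrl / peak  # bounded in [-1, 1] after centring
        pert = np.interp(x, ctrl_x, ctrl) * roughness_px
    else:
        pert = np.zeros(n_pts)
    b = BoundaryPolyline(vertices=np.column_stack([x, gap_px + pert]))
    return InterfaceRegion(
        membrane_a=a,
        membrane_b=b,
        region_length_px=int(region_length_px),
        px_size_nm=px_size_nm,
    )


def make_point_cloud(
    n_main: int,
    n_ectopic: int,
    cluster_radius: float = 20.0,
    ectopic_offset: float = 100.0,
    seed: int = 0,
) -> LabeledPointCloud:
    """Main cluster in a ball plus ectopic points displaced from its centre.

    Main points are uniform in a ball of `cluster_radius` about the origin;
    ectopic points lie at distances in [offset, 1.5·offset] from the centre
    in random directions. Requires ``ectopic_offset > 2·cluster_radius`` so
    the fixture is unambiguous; truth flags are recorded on the output.
    """
    if n_main < 0 or n_ectopic < 0:
        raise ValueError("counts must be >= 0")
    if n_ectopic > 0 and ectopic_offset <= 2.0 * cluster_radius:
        raise ValueError("ectopic_offset must exceed 2 x cluster_radius")
    rng = np.random.default_rng(seed)

    def _ball(n: int, radius: float) -> np.ndarray:
        if n == 0:
            return np.empty((0, 3))
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = radius * rng.uniform(0.0, 1.0, size=(n, 1)) ** (1.0 / 3.0)
        return u * r

    main = _ball(n_main, cluster_radius)
    if n_ectopic:
        direction = rng.normal(size=(n_ectopic, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        dist = rng.uniform(ectopic_offset, 1.5 * ectopic_offset, size=(n_ectopic, 1))
        ectopic = direction * dist
    else:
        ectopic = np.empty((0, 3))
    points = np.vstack([main, ectopic])
    flags = ("main",) * n_main + ("ectopic",) * n_ectopic
    return LabeledPointCloud(points=points, flags=flags, marker="synthetic")
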