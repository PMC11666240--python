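"""Data model and I/O for 3D cell tracks, point clouds, boundary polylines and masks.

The coordinate convention used throughout the package is

* ``x`` = mediolateral (ML), positive towards lateral, in micrometres;
* ``y`` = dorsoventral (DV), positive towards dorsal, in micrometres;
* ``z`` = anteroposterior (AP), positive towards anterior, in micrometres.

Label masks use 0-based pixel indices with axis 0 = DV (rows) and axis 1 = ML
(columns); polylines extracted from masks are expressed in micrometres.

Two track-table dialects are supported: the package's native CSV
(``track_id,cohort,embryo_id,side,t_min,x_um,y_um,z_um``) and the table
exported by the Fiji/ImageJ "Manual Tracking" plugin
(``Track n°,Slice n°,X,Y[,Z]``), for which the frame interval and pixel size
must be supplied by the caller because the export does not carry them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COHORTS",
    "SIDES",
    "AXES_CONVENTION",
    "TimedTrack",
    "TrackSet",
    "LabeledPointCloud",
    "BoundaryPolyline",
    "InterfaceRegion",
    "TrackFormatError",
    "TrackValidationError",
    "EmptyInputError",
    "read_tracks",
    "write_tracks",
    "boundary_from_mask",
    "read_mask",
    "read_polyline",
    "write_polyline",
]

logger = logging.getLogger(__name__)

COHORTS = ("op_cell", "brain_cell", "growth_cone", "ncc", "other")
SIDES = ("left", "right", "unspecified")

#: Fixed axis semantics carried by every TrackSet.
AXES_CONVENTION: Mapping[str, str] = {
    "ml": "+x lateral",
    "dv": "+y dorsal",
    "ap": "+z anterior",
}

NATIVE_COLUMNS = (
    "track_id",
    "cohort",
    "embryo_id",
    "side",
    "t_min",
    "x_um",
    "y_um",
    "z_um",
)


class TrackFormatError(ValueError):
    """A track file does not conform to the declared dialect."""


class TrackValidationError(ValueError):
    """A parsed track violates a data-model invariant."""


class EmptyInputError(ValueError):
    """An input file or selection contains no usable records."""


@dataclass(frozen=True)
class TimedTrack:
    """One object's time-ordered 3D positions.

    Parameters
    ----------
    track_id : str
        Identifier, unique within a :class:`TrackSet`.
    cohort : str
        One of ``op_cell``, ``brain_cell``, ``growth_cone``, ``ncc``, ``other``.
    t : ndarray, shape (n,)
        Sample times in minutes, strictly increasing.
    xyz : ndarray, shape (n, 3)
        Positions in micrometres, columns (ML, DV, AP).
    embryo_id, side : str
        Provenance labels.
    """

    track_id: str
    cohort: str
    t: np.ndarray
    xyz: np.ndarray
    embryo_id: str = ""
    side: str = "unspecified"

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        xyz = np.asarray(self.xyz, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "xyz", xyz)
        if self.cohort not in COHORTS:
            raise TrackValidationError(
                f"track {self.track_id!r}: unknown cohort {self.cohort!r}"
            )
        if self.side not in SIDES:
            raise TrackValidationError(
                f"track {self.track_id!r}: unknown side {self.side!r}"
            )
        if t.ndim != 1 or xyz.shape != (t.size, 3):
            raise TrackValidationError(
                f"track {self.track_id!r}: shape mismatch t{t.shape} xyz{xyz.shape}"
            )
        if t.size == 0:
            raise TrackValidationError(f"track {self.track_id!r}: no samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(xyz))):
            raise TrackValidationError(
                f"track {self.track_id!r}: non-finite time or coordinate"
            )
        if np.any(np.diff(t) <= 0):
            raise TrackValidationError(
                f"track {self.track_id!r}: time not strictly increasing"
            )

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def frame_indices(self, dt: float) -> np.ndarray:
        """Integer frame numbers ``round(t / dt)``; gaps appear as missing ints."""
        f = np.rint(self.t / dt)
        if not np.allclose(f * dt, self.t, atol=1e-6 * dt):
            raise TrackValidationError(
                f"track {self.track_id!r}: sample times are not multiples of dt={dt}"
            )
        return f.astype(np.int64)


@dataclass(frozen=True)
class TrackSet:
    """A collection of tracks sharing one nominal frame interval."""

    tracks: tuple[TimedTrack, ...]
    dt_nominal: float
    axes_convention: Mapping[str, str] = field(
        default_factory=lambda: dict(AXES_CONVENTION)
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "tracks", tuple(self.tracks))
        if self.dt_nominal <= 0:
            raise TrackValidationError("dt_nominal must be positive")
        for tr in self.tracks:
            tr.frame_indices(self.dt_nominal)  # raises if incompatible

    def __len__(self) -> int:
        return len(self.tracks)

    def select(self, cohort: str | Sequence[str] | None = None) -> tuple[TimedTrack, ...]:
        if cohort is None:
            return self.tracks
        wanted = {cohort} if isinstance(cohort, str) else set(cohort)
        return tuple(tr for tr in self.tracks if tr.cohort in wanted)

    def time_span(self) -> tuple[float, float]:
        if not self.tracks:
            raise EmptyInputError("empty TrackSet has no time span")
        return (
            min(float(tr.t[0]) for tr in self.tracks),
            max(float(tr.t[-1]) for tr in self.tracks),
        )


@dataclass(frozen=True)
class LabeledPointCloud:
    """Cell centroids in micrometres with a main-cluster / ectopic partition."""

    points: np.ndarray  # (n, 3) µm
    flags: tuple[str, ...]  # per point: "main" | "ectopic"
    marker: str = ""

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "flags", tuple(self.flags))
        if pts.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if len(self.flags) != pts.shape[0]:
            raise ValueError("flags must parallel points")
        bad = set(self.flags) - {"main", "ectopic"}
        if bad:
            raise ValueError(f"unknown flags: {sorted(bad)}")

    @property
    def main_points(self) -> np.ndarray:
        mask = np.array([f == "main" for f in self.flags], dtype=bool)
        return self.points[mask]

    @property
    def n_ectopic(self) -> int:
        return sum(f == "ectopic" for f in self.flags)


@dataclass(frozen=True)
class BoundaryPolyline:
    """Ordered open 2D curve (ML, DV) of a segmented tissue frontier, in µm.

    Boundaries extracted from masks are ordered ventral→dorsal so that the
    first/last vertices are the ventral-most/dorsal-most points by
    construction.
    """

    vertices: np.ndarray  # (n, 2) columns (ml, dv)
    closed: bool = False

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        object.__setattr__(self, "vertices", v)
        if self.closed:
            raise ValueError("boundary polylines are open curves")
        if v.shape[0] < 2 or v.shape[1] != 2:
            raise ValueError("polyline needs >= 2 (ml, dv) vertices")
        if np.any(np.all(np.diff(v, axis=0) == 0.0, axis=1)):
            raise ValueError("consecutive vertices must be distinct")

    @property
    def arc_length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.vertices, axis=0).T)))

    @property
    def ml(self) -> np.ndarray:
        return self.vertices[:, 0]

    @property
    def dv(self) -> np.ndarray:
        return self.vertices[:, 1]


@dataclass(frozen=True)
class InterfaceRegion:
    """Paired membranes bounding an intercellular gap, in pixel units."""

    membrane_a: BoundaryPolyline
    membrane_b: BoundaryPolyline
    region_length_px: int
    px_size_nm: float

    def __post_init__(self) -> None:
        if self.region_length_px <= 0:
            raise ValueError("region_length_px must be positive")
        if self.px_size_nm <= 0:
            raise ValueError("px_size_nm must be positive")


# ---------------------------------------------------------------------------
# Track tables


def _validate_native_frame(df: pd.DataFrame, path: Path) -> None:
    missing = [c for c in NATIVE_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )


def _infer_dt(tracks: Sequence[TimedTrack], dt: float | None) -> float:
    if dt is not None:
        return float(dt)
    diffs = np.concatenate(
        [np.diff(tr.t) for tr in tracks if tr.n_samples >= 2] or [np.array([])]
    )
    if diffs.size == 0:
        raise TrackValidationError(
            "cannot infer dt_nominal: no track has two samples; pass dt explicitly"
        )
    return float(diffs.min())


def read_tracks(
    path: str | Path,
    dialect: str = "native",
    *,
    dt: float | None = None,
    pixel_size_um: float | None = None,
) -> TrackSet:
    """Read a track table into a :class:`TrackSet`.

    Parameters
    ----------
    path : path
        CSV file.
    dialect : {"native", "fiji_manual_tracking"}
        ``native`` expects the package's own columns. ``fiji_manual_tracking``
        expects the Manual Tracking plugin export and requires `dt` (minutes
        per slice) and `pixel_size_um`; slice ``s`` maps to ``t = (s - 1) * dt``
        and pixel coordinates are scaled to micrometres. A missing Z column is
        accepted and filled with ``z = 0`` (the analysis then degrades to 2D;
        a warning is logged).
    dt : float, optional
        Frame interval in minutes. For the native dialect it is inferred from
        the data when omitted.
    pixel_size_um : float, optional
        Pixel size of the movie; required for the Fiji dialect and never
        defaulted (it is not recorded in the export).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "native":
        df = pd.read_csv(path, dtype={"track_id": str, "embryo_id": str})
        _validate_native_frame(df, path)
        if df.empty:
            return TrackSet(tracks=(), dt_nominal=dt if dt is not None else 1.0)
        tracks = []
        for tid, g in df.groupby("track_id", sort=True):
            if np.any(np.diff(g["t_min"].to_numpy(float)) <= 0):
                raise TrackValidationError(
                    f"track {str(tid)!r}: non-monotonic time in {path}"
                )
            tracks.append(
                TimedTrack(
                    track_id=str(tid),
                    cohort=str(g["cohort"].iloc[0]),
                    t=g["t_min"].to_numpy(float),
                    xyz=g[["x_um", "y_um", "z_um"]].to_numpy(float),
                    embryo_id=str(g["embryo_id"].iloc[0]),
                    side=str(g["side"].iloc[0]),
                )
            )
        return TrackSet(tracks=tuple(tracks), dt_nominal=_infer_dt(tracks, dt))
    if dialect == "fiji_manual_tracking":
        if dt is None or pixel_size_um is None:
            raise ValueError(
                "fiji_manual_tracking dialect requires dt and pixel_size_um"
            )
        df = pd.read_csv(path)
        for col in ("Track n°", "Slice n°", "X", "Y"):
            if col not in df.columns:
                raise TrackFormatError(f"{path}: missing required column {col!r}")
        if df.empty:
            raise EmptyInputError(f"{path}: no rows")
        has_z = "Z" in df.columns
        if not has_z:
            logger.warning(
                "%s: no Z column; filling z=0 (analysis degrades to 2D)", path
            )
        tracks = []
        for tid, g in df.groupby("Track n°", sort=True):
            sl = g["Slice n°"].to_numpy(float)
            if np.any(np.diff(sl) <= 0):
                raise TrackValidationError(
                    f"track {str(tid)!r}: non-monotonic slice order in {path}"
                )
            t = (sl - 1.0) * dt
            xyz = np.column_stack(
                [
                    g["X"].to_numpy(float) * pixel_size_um,
                    g["Y"].to_numpy(float) * pixel_size_um,
                    (g["Z"].to_numpy(float) * pixel_size_um) if has_z else np.zeros(len(g)),
                ]
            )
            tracks.append(
                TimedTrack(track_id=str(tid), cohort="other", t=t, xyz=xyz)
            )
        return TrackSet(tracks=tuple(tracks), dt_nominal=float(dt))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_tracks(ts: TrackSet, path: str | Path) -> Path:
    """Write a TrackSet as a native-dialect CSV; inverse of :func:`read_tracks`."""
    path = Path(path)
    rows = []
    for tr in ts.tracks:
        for i in range(tr.n_samples):
            rows.append(
                (
                    tr.track_id,
                    tr.cohort,
                    tr.embryo_id,
                    tr.side,
                    tr.t[i],
                    tr.xyz[i, 0],
                    tr.xyz[i, 1],
                    tr.xyz[i, 2],
                )
            )
    df = pd.DataFrame(rows, columns=list(NATIVE_COLUMNS))
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Boundary extraction from label masks


def boundary_from_mask(
    mask: np.ndarray,
    roi: tuple[int, int, int, int],
    label_a: int,
    label_b: int,
    pixel_size_um: float = 1.0,
) -> BoundaryPolyline:
    """Trace the interface between two labels inside a rectangular ROI.

    The interface is the chain of pixel edges separating 4-adjacent pixels of
    `label_a` and `label_b`. The returned polyline runs through the grid
    corners of that chain and the midpoint of every interface pixel-edge, so
    its arc length equals (number of interface edges) x pixel size exactly.
    Vertices are ordered ventral→dorsal (increasing DV = increasing row index)
    and scaled to micrometres.

    Parameters
    ----------
    mask : 2D integer array
        Label image, axis 0 = DV, axis 1 = ML.
    roi : (row_start, row_stop, col_start, col_stop)
        Half-open rectangle, numpy slicing convention.
    label_a, label_b : int
        The two tissue labels whose shared frontier is traced.
    pixel_size_um : float
        Isotropic pixel size.

    Raises
    ------
    ValueError
        If a label is absent in the ROI, or the interface has more than one
        connected component (the ROI must then be tightened).
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2D label image")
    r0, r1, c0, c1 = roi
    sub = mask[r0:r1, c0:c1]
    for lab in (label_a, label_b):
        if not np.any(sub == lab):
            raise ValueError(f"label {lab} absent in ROI")

    a = sub == label_a
    b = sub == label_b
    # Interface edges between 4-adjacent a/b pixels, as grid-corner segments.
    # Corner (i, j) sits at the top-left of pixel (i, j).
    edges: list[tuple[tuple[int, int], tuple[int, int]]] = []
    horiz = (a[:, :-1] & b[:, 1:]) | (b[:, :-1] & a[:, 1:])
    for i, j in zip(*np.nonzero(horiz)):
        edges.append(((i, j + 1), (i + 1, j + 1)))  # vertical segment
    vert = (a[:-1, :] & b[1:, :]) | (b[:-1, :] & a[1:, :])
    for i, j in zip(*np.nonzero(vert)):
        edges.append(((i + 1, j), (i + 1, j + 1)))  # horizontal segment
    if not edges:
        raise ValueError(
            f"labels {label_a} and {label_b} share no interface in ROI"
        )

    adjacency: dict[tuple[int, int], list[int]] = {}
    for k, (p, q) in enumerate(edges):
        adjacency.setdefault(p, []).append(k)
        adjacency.setdefault(q, []).append(k)

    # Walk the edge chain; count connected components of the edge graph.
    seen = [False] * len(edges)
    components = 0
    path_corners: list[tuple[int, int]] | None = None
    for start_edge in range(len(edges)):
        if seen[start_edge]:
            continue
        components += 1
        # find a degree-1 corner in this component to start an open walk
        stack = [start_edge]
        comp_edges = []
        while stack:
            e = stack.pop()
            if seen[e]:
                continue
            seen[e] = True
            comp_edges.append(e)
            for corner in edges[e]:
                stack.extend(adjacency[corner])
        endpoints = [
            c
            for c in {c for e in comp_edges for c in edges[e]}
            if len(adjacency[c]) == 1
        ]
        if components == 1:
            if not endpoints:
                raise ValueError("interface forms a closed loop inside ROI")
            # ordered corner walk from one endpoint
            used = set()
            corner = min(endpoints)
            chain = [corner]
            while True:
                nxt = [e for e in adjacency[corner] if e not in used]
                if not nxt:
                    break
                e = nxt[0]
                used.add(e)
                p, q = edges[e]
                corner = q if p == corner else p
                chain.append(corner)
            if len(chain) != len(comp_edges) + 1:
                raise ValueError(
                    "interface branches inside ROI; tighten the ROI"
                )
            path_corners = chain
    if components > 1:
        raise ValueError(
            f"interface has {components} disjoint components in ROI; tighten the ROI"
        )
    assert path_corners is not None

    # Interleave corners with edge midpoints; convert (row, col) -> (ml, dv) µm.
    pts: list[tuple[float, float]] = []
    for k, (i, j) in enumerate(path_corners):
        pts.append((float(j), float(i)))
        if k + 1 < len(path_corners):
            ni, nj = path_corners[k + 1]
            pts.append(((j + nj) / 2.0, (i + ni) / 2.0))
    arr = np.asarray(pts)
    # offset to absolute pixel coordinates, then scale
    arr[:, 0] = (arr[:, 0] + c0) * pixel_size_um  # ml
    arr[:, 1] = (arr[:, 1] + r0) * pixel_size_um  # dv
    if arr[0, 1] > arr[-1, 1]:
        arr = arr[::-1]
    return BoundaryPolyline(vertices=arr)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel TIFF label image as a 2D integer array."""
    import tifffile

    arr = np.asarray(tifffile.imread(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2D label image, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: label image must have an integer dtype, got {arr.dtype}")
    return arr


def read_polyline(path: str | Path) -> BoundaryPolyline:
    """Read a 2-column CSV (ml_um, dv_um) polyline."""
    df = pd.read_csv(path)
    for col in ("ml_um", "dv_um"):
        if col not in df.columns:
            raise TrackFormatError(f"{path}: missing required column {col!r}")
    return BoundaryPolyline(vertices=df[["ml_um", "dv_um"]].to_numpy(float))


def write_polyline(poly: BoundaryPolyline, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(poly.vertices, columns=["ml_um", "dv_um"]).to_csv(path, index=False)
    return path
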