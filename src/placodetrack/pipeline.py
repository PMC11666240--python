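"""Configuration-driven orchestration of the analyses, group comparisons and
plot export.

A YAML configuration selects stages (msd, summaries, circ_anova, extents,
distortion, thickness) and their parameters; inputs may be files in the
package's formats or synthetic cohorts generated in-run from a seed. Outputs
are tidy CSVs and JSON summaries, deterministic for a given config and seed
(no timestamps are written into result files).

Two-group comparisons follow the convention of checking normality first:
Shapiro–Wilk at α = 0.05 per group, with the unpaired two-tailed t test when
both groups pass and the Mann–Whitney U test otherwise. The choice is
recorded and can be overridden, in which case a warning is logged. No
multiple-testing correction is applied; p-values are per comparison.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import circular_stats, kinematics, morphometry, synthetic_data, tracks_io

__all__ = [
    "AnalysisConfig",
    "GroupComparison",
    "PipelineError",
    "run_pipeline",
    "compare_groups",
    "export_rose_plot",
    "export_msd_plot",
]

logger = logging.getLogger(__name__)

_KNOWN_STAGES = ("msd", "summaries", "drift", "circ_anova", "extents", "distortion", "thickness")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending input."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Declarative description of one analysis run."""

    stages: Mapping[str, Mapping[str, Any]]
    out_dir: str
    seed: int = 0
    tracks_path: str | None = None
    synthetic: Mapping[str, Any] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            stages=raw.get("stages", {}),
            out_dir=raw["out_dir"],
            seed=int(raw.get("seed", 0)),
            tracks_path=raw.get("tracks_path"),
            synthetic=raw.get("synthetic"),
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "stages": {k: dict(v) for k, v in self.stages.items()},
            "out_dir": self.out_dir,
            "seed": self.seed,
            "tracks_path": self.tracks_path,
            "synthetic": dict(self.synthetic) if self.synthetic else None,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
        return path

    def validate(self) -> None:
        for name in self.stages:
            if name not in _KNOWN_STAGES:
                raise ValueError(f"unknown stage {name!r}; known: {_KNOWN_STAGES}")
        if self.tracks_path is not None and not Path(self.tracks_path).exists():
            raise FileNotFoundError(self.tracks_path)
        needs_tracks = {"msd", "summaries", "drift", "circ_anova"} & set(self.stages)
        if needs_tracks and self.tracks_path is None and self.synthetic is None:
            raise ValueError(
                f"stages {sorted(needs_tracks)} need tracks_path or a synthetic block"
            )


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison with a declared normality-driven test choice."""

    metric: str
    group_names: tuple[str, str]
    group_means: tuple[float, float]
    group_sems: tuple[float, float]
    n: tuple[int, int]
    test: str  # "t_two_tailed" | "mann_whitney"
    statistic: float
    p_value: float
    normality_p: tuple[float, float]
    forced: bool = False


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    force_test: str | None = None,
    metric: str = "",
) -> GroupComparison:
    """Two-group test with a Shapiro–Wilk normality pre-check.

    Both groups must pass Shapiro–Wilk at α = 0.05 (and have n >= 3 for the
    check to run) for the unpaired two-tailed t test; otherwise the
    Mann–Whitney U test is used. `force_test` overrides the choice with a
    logged warning.
    """
    if len(values_by_group) != 2:
        raise ValueError("compare_groups needs exactly 2 groups")
    (na, xa), (nb, xb) = [
        (k, np.asarray(v, dtype=float)) for k, v in values_by_group.items()
    ]
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each group needs n >= 2")

    def _shapiro_p(x: np.ndarray) -> float:
        if x.size < 3 or np.ptp(x) == 0:
            return 0.0  # cannot assert normality
        return float(stats.shapiro(x).pvalue)

    pa, pb = _shapiro_p(xa), _shapiro_p(xb)
    chosen = "t_two_tailed" if (pa > 0.05 and pb > 0.05) else "mann_whitney"
    forced = False
    if force_test is not None:
        if force_test not in ("t_two_tailed", "mann_whitney"):
            raise ValueError(f"unknown test {force_test!r}")
        if force_test != chosen:
            logger.warning(
                "forcing %s although the normality pre-check selected %s",
                force_test,
                chosen,
            )
            forced = True
        chosen = force_test
    if chosen == "t_two_tailed":
        if np.ptp(xa) == 0 and np.ptp(xb) == 0:
            if np.allclose(xa.mean(), xb.mean()):
                statistic, p = 0.0, 1.0
            else:
                raise ValueError("zero variance in both groups: t test undefined")
        else:
            res = stats.ttest_ind(xa, xb, equal_var=True)
            statistic, p = float(res.statistic), float(res.pvalue)
    else:
        n_tot = xa.size + xb.size
        if n_tot <= 16:
            # small samples: exhaustive permutation null (exact even with ties)
            from math import comb

            method = stats.PermutationMethod(
                n_resamples=comb(n_tot, int(xa.size)) + 1,
                rng=np.random.default_rng(0),
            )
        else:
            method = "auto"
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        statistic, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        metric=metric,
        group_names=(na, nb),
        group_means=(float(xa.mean()), float(xb.mean())),
        group_sems=(_sem(xa), _sem(xb)),
        n=(int(xa.size), int(xb.size)),
        test=chosen,
        statistic=statistic,
        p_value=min(p, 1.0),
        normality_p=(pa, pb),
        forced=forced,
    )


# ---------------------------------------------------------------------------
# Plot export


def export_rose_plot(
    counts: np.ndarray, edges: np.ndarray, path: str | Path
) -> tuple[Path, Path]:
    """Polar rose plot (SVG) plus the underlying per-bin CSV."""
    counts = np.asarray(counts)
    edges = np.asarray(edges)
    if counts.size + 1 != edges.size:
        raise ValueError("edges must bracket counts")
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    df = pd.DataFrame(
        {
            "bin_start_deg": np.rad2deg(edges[:-1]),
            "bin_end_deg": np.rad2deg(edges[1:]),
            "count": counts,
        }
    )
    df.to_csv(csv_path, index=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    centers = (edges[:-1] + edges[1:]) / 2
    # dorsal (0°) at the top, angles clockwise to match the ML-DV convention
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.bar(centers, counts, width=np.diff(edges), align="center", alpha=0.7)
    fig.savefig(path, format="svg")
    plt.close(fig)
    return path, csv_path


def export_msd_plot(
    curves: Mapping[str, kinematics.MsdCurve], path: str | Path
) -> tuple[Path, Path]:
    """MSD(τ) curves (SVG) plus the underlying tidy CSV (one row per lag)."""
    if not curves or all(c.lags.size == 0 for c in curves.values()):
        raise ValueError("no MSD data to export")
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    rows = []
    for name, c in curves.items():
        for i in range(c.lags.size):
            rows.append((name, c.lags[i], c.msd[i], int(c.n_pairs[i]), c.n_tracks))
    pd.DataFrame(
        rows, columns=["curve", "lag_min", "msd_um2", "n_pairs", "n_tracks"]
    ).to_csv(csv_path, index=False)
    fig, ax = plt.subplots()
    for name, c in curves.items():
        ax.plot(c.lags, c.msd, marker="o", label=name)
    ax.set_xlabel("lag τ (min)")
    ax.set_ylabel("MSD (µm²)")
    ax.legend()
    fig.savefig(path, format="svg")
    plt.close(fig)
    return path, csv_path


# ---------------------------------------------------------------------------
# Pipeline


def _load_tracks(config: AnalysisConfig) -> tracks_io.TrackSet:
    if config.tracks_path is not None:
        return tracks_io.read_tracks(config.tracks_path)
    assert config.synthetic is not None
    syn = dict(config.synthetic)
    op_cfg = synthetic_data.WalkConfig(**syn.get("op", {}), seed=config.seed)
    brain_cfg = synthetic_data.WalkConfig(
        **syn.get("brain", {}), seed=config.seed + 1
    )
    shared = syn.get("shared_drift")
    return synthetic_data.simulate_cohorts(
        op_cfg, brain_cfg, shared_drift=tuple(shared) if shared else None
    )


def run_pipeline(config: AnalysisConfig) -> dict[str, Path]:
    """Execute the selected stages and write one tidy output file per stage.

    Stage outputs land in ``config.out_dir`` together with a run-manifest
    JSON recording the seed, parameters and package version. Outputs are
    byte-identical across runs of the same config and seed. A stage failure
    aborts the run with the stage name; files already written stay on disk
    and the manifest is marked incomplete (it is written last on success).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    tracks: tracks_io.TrackSet | None = None
    needs_tracks = {"msd", "summaries", "drift", "circ_anova"} & set(config.stages)
    if needs_tracks:
        tracks = _load_tracks(config)

    for stage, params in config.stages.items():
        params = dict(params)
        try:
            if stage == "msd":
                curve = kinematics.msd(
                    tracks,
                    cohort=params.get("cohort"),
                    max_lag_fraction=params.get("max_lag_fraction", 0.5),
                )
                p = out / "msd.csv"
                pd.DataFrame(
                    {
                        "lag_min": curve.lags,
                        "msd_um2": curve.msd,
                        "n_pairs": curve.n_pairs,
                        "n_tracks": curve.n_tracks,
                    }
                ).to_csv(p, index=False)
                artifacts[stage] = p
            elif stage == "drift":
                ds = kinematics.drift_series(
                    tracks, reference_cohort=params.get("reference_cohort", "op_cell")
                )
                p = out / "drift.csv"
                pd.DataFrame(
                    {
                        "t_min": ds.frames,
                        "step_ml_um": ds.mean_step[:, 0],
                        "step_dv_um": ds.mean_step[:, 1],
                        "step_ap_um": ds.mean_step[:, 2],
                        "n_cells": ds.n_cells,
                    }
                ).to_csv(p, index=False)
                artifacts[stage] = p
            elif stage == "summaries":
                drift = None
                if params.get("reference_cohort"):
                    drift = kinematics.drift_series(
                        tracks, reference_cohort=params["reference_cohort"]
                    )
                sums = kinematics.windowed_summaries(
                    tracks,
                    t_start=params.get("t_start", 0.0),
                    window_len=params["window_len"],
                    n_windows=params["n_windows"],
                    drift=drift,
                    cohort=params.get("cohort"),
                    plane=params.get("plane", "ml_dv"),
                )
                p = out / "summaries.csv"
                pd.DataFrame(
                    [
                        {
                            "track_id": s.track_id,
                            "cohort": s.cohort,
                            "window_start_min": s.window[0],
                            "window_end_min": s.window[1],
                            "mean_speed_um_per_min": s.mean_speed,
                            "persistence": s.persistence,
                            "path_length_um": s.path_length,
                            "net_ml_um": s.net_displacement[0],
                            "net_dv_um": s.net_displacement[1],
                            "net_ap_um": s.net_displacement[2],
                            "orientation_deg": s.orientation_deg,
                        }
                        for s in sums
                    ]
                ).to_csv(p, index=False)
                artifacts[stage] = p
            elif stage == "circ_anova":
                sums = kinematics.windowed_summaries(
                    tracks,
                    t_start=params.get("t_start", 0.0),
                    window_len=params["window_len"],
                    n_windows=params["n_windows"],
                    cohort=params.get("cohort"),
                    plane=params.get("plane", "ml_dv"),
                )
                angles, groups = [], []
                group_by = params.get("group_by", "cohort")
                for s in sums:
                    if np.isnan(s.orientation_deg):
                        continue
                    angles.append(np.deg2rad(s.orientation_deg))
                    groups.append(getattr(s, group_by))
                sample = circular_stats.CircularSample(
                    angles=circular_stats.wrap_angle(np.asarray(angles)),
                    groups=tuple(groups),
                )
                res = circular_stats.circ_anova_lrt(sample)
                p = out / "circ_anova.json"
                payload = {
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                    "kappa": res.pooled_fit.kappa,
                    "kappa_treatment": res.kappa_treatment,
                    "group_mus_deg": {
                        g: float(np.rad2deg(f.mu)) for g, f in res.group_fits.items()
                    },
                }
                p.write_text(json.dumps(payload, sort_keys=True, indent=2))
                artifacts[stage] = p
            elif stage == "extents":
                if "cloud_path" in params:
                    df = pd.read_csv(params["cloud_path"])
                    cloud = tracks_io.LabeledPointCloud(
                        points=df[["x_um", "y_um", "z_um"]].to_numpy(float),
                        flags=tuple(df["flag"]),
                    )
                else:
                    cloud = synthetic_data.make_point_cloud(
                        n_main=params.get("n_main", 30),
                        n_ectopic=params.get("n_ectopic", 3),
                        cluster_radius=params.get("cluster_radius", 20.0),
                        ectopic_offset=params.get("ectopic_offset", 100.0),
                        seed=config.seed,
                    )
                if params.get("auto_flag"):
                    cloud = morphometry.flag_ectopic(
                        cloud, link_dist=params.get("link_dist", morphometry.DEFAULT_LINK_DIST_UM)
                    )
                box = morphometry.extent_box(cloud)
                p = out / "extents.csv"
                pd.DataFrame([dataclasses.asdict(box)]).to_csv(p, index=False)
                artifacts[stage] = p
            elif stage == "distortion":
                if "boundary_path" in params:
                    poly = tracks_io.read_polyline(params["boundary_path"])
                else:
                    poly = synthetic_data.make_boundary(
                        synthetic_data.BoundaryConfig(
                            amplitude=params.get("amplitude", 5.0),
                            n_waves=params.get("n_waves", 3),
                            dv_span=params.get("dv_span", 100.0),
                            n_vertices=params.get("n_vertices", 500),
                            seed=config.seed,
                        )
                    )
                di = morphometry.distortion_index(poly)
                p = out / "distortion.csv"
                pd.DataFrame([dataclasses.asdict(di)]).to_csv(p, index=False)
                artifacts[stage] = p
            elif stage == "thickness":
                region = synthetic_data.make_interface(
                    gap_px=params.get("gap_px", 120.0),
                    region_length_px=params.get("region_length_px", 1000),
                    roughness_px=params.get("roughness_px", 0.0),
                    seed=config.seed,
                    px_size_nm=params.get("px_size_nm", 1.0),
                )
                summ = morphometry.interface_thickness(
                    region, step_px=params.get("step_px", 100)
                )
                p = out / "thickness.csv"
                pd.DataFrame(
                    {
                        "region_mean_nm": summ.per_region_means,
                        "n_samples": summ.samples_per_region,
                    }
                ).to_csv(p, index=False)
                artifacts[stage] = p
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    from . import __version__

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": {k: dict(v) for k, v in config.stages.items()},
        "outputs": {k: str(v.name) for k, v in artifacts.items()},
    }
    mpath = out / "run_manifest.json"
    mpath.write_text(json.dumps(manifest, sort_keys=True, indent=2))
    artifacts["manifest"] = mpath
    return artifacts
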