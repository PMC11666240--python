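"""Morphometry: extents, ectopic flagging, brain width, distortion, thickness."""

from __future__ import annotations

import numpy as np
import pytest

from placodetrack import (
    BoundaryPolyline,
    LabeledPointCloud,
    brain_width,
    distortion_index,
    extent_box,
    flag_ectopic,
    interface_thickness,
    make_interface,
    thickness_embryo_mean,
)

from conftest import connected_components_bruteforce


# --- extents ----------------------------------------------------------------


def _cloud(points, flags=None):
    points = np.asarray(points, float)
    if flags is None:
        flags = ("main",) * points.shape[0]
    return LabeledPointCloud(points=points, flags=flags)


def test_extent_box_max_minus_min():
    box = extent_box(_cloud([[0, 0, 0], [4, 1, 0], [2, 5, 0]]))
    assert (box.ml, box.dv, box.ap) == (4, 5, 0)
    assert box.n_points_used == 3
    assert box.n_ectopic_excluded == 0


def test_extent_box_ignores_ectopic_points():
    pts = [[0, 0, 0], [4, 1, 0], [2, 5, 0], [30, 0, 0]]
    box = extent_box(_cloud(pts, ("main", "main", "main", "ectopic")))
    assert (box.ml, box.dv, box.ap) == (4, 5, 0)
    assert box.n_ectopic_excluded == 1


def test_extent_box_single_point_degenerate():
    box = extent_box(_cloud([[1, 2, 3]]))
    assert (box.ml, box.dv, box.ap) == (0, 0, 0)


def test_extent_box_requires_main_points():
    with pytest.raises(ValueError, match="main"):
        extent_box(_cloud([[0, 0, 0]], ("ectopic",)))


def test_extent_box_invariant_under_permutation_and_ectopic_addition(rng):
    pts = rng.normal(0, 10, size=(12, 3))
    base = extent_box(_cloud(pts))
    perm = rng.permutation(12)
    permuted = extent_box(_cloud(pts[perm]))
    extended = extent_box(
        _cloud(np.vstack([pts, [[500, 500, 500]]]), ("main",) * 12 + ("ectopic",))
    )
    for other in (permuted, extended):
        assert (other.ml, other.dv, other.ap) == (base.ml, base.dv, base.ap)


# --- ectopic flagging -------------------------------------------------------


def test_two_blobs_far_apart_smaller_is_ectopic(rng):
    big = rng.normal(0, 3, size=(10, 3))
    small = rng.normal(0, 3, size=(4, 3)) + 100.0
    out = flag_ectopic(_cloud(np.vstack([big, small])), link_dist=20.0)
    assert out.flags[:10] == ("main",) * 10
    assert out.flags[10:] == ("ectopic",) * 4


def test_chained_points_form_one_component():
    pts = np.column_stack([np.arange(10) * 5.0, np.zeros(10), np.zeros(10)])
    out = flag_ectopic(_cloud(pts), link_dist=6.0)
    assert out.n_ectopic == 0


def test_equal_size_tie_goes_to_medoid_component():
    # 5+5 points; the global medoid lies in the first (tighter) cluster
    a = np.column_stack([np.linspace(0, 1, 5), np.zeros(5), np.zeros(5)])
    b = np.column_stack([np.linspace(100, 120, 5), np.zeros(5), np.zeros(5)])
    out = flag_ectopic(_cloud(np.vstack([a, b])), link_dist=30.0)
    d = np.linalg.norm(
        np.vstack([a, b])[:, None] - np.vstack([a, b])[None], axis=2
    ).sum(1)
    medoid = int(np.argmin(d))
    expected_main = "main" if medoid < 5 else "ectopic"
    assert out.flags[0] == expected_main
    # deterministic under repeated calls
    again = flag_ectopic(_cloud(np.vstack([a, b])), link_dist=30.0)
    assert out.flags == again.flags


def test_flag_ectopic_agrees_with_bruteforce_components(rng):
    for _ in range(30):
        n = int(rng.integers(2, 50))
        pts = rng.uniform(-50, 50, size=(n, 3))
        link = float(rng.uniform(5, 40))
        out = flag_ectopic(_cloud(pts), link_dist=link)
        labels = connected_components_bruteforce(pts, link)
        main_labels = {labels[i] for i, f in enumerate(out.flags) if f == "main"}
        assert len(main_labels) == 1  # main points form exactly one component
        comp_sizes = np.bincount(labels, minlength=n)
        main_size = sum(f == "main" for f in out.flags)
        assert main_size == comp_sizes.max()


def test_flag_ectopic_rejects_bad_threshold():
    with pytest.raises(ValueError):
        flag_ectopic(_cloud([[0, 0, 0], [1, 1, 1]]), link_dist=0.0)


# --- brain width ------------------------------------------------------------


def _vertical_wall(ml, dv_lo=0.0, dv_hi=100.0):
    return BoundaryPolyline(vertices=[[ml, dv_lo], [ml, dv_hi]])


def test_parallel_walls_constant_width():
    left = {ap: _vertical_wall(-20.0) for ap in (0.0, 50.0, 100.0)}
    right = {ap: _vertical_wall(20.0) for ap in (0.0, 50.0, 100.0)}
    levels = [(ap, dv) for ap in (0.0, 50.0, 100.0) for dv in (10.0, 50.0, 90.0)]
    prof = brain_width(left, right, levels)
    np.testing.assert_allclose(prof.widths, 40.0)
    assert len(prof.levels) == 9


def test_tilted_wall_linear_interpolation():
    left = {0.0: _vertical_wall(-20.0)}
    right = {0.0: BoundaryPolyline(vertices=[[20.0, 0.0], [10.0, 100.0]])}
    prof = brain_width(left, right, [(0.0, 50.0)])
    assert prof.widths[0] == pytest.approx(35.0)


def test_level_outside_span_errors():
    left = {0.0: _vertical_wall(-20.0)}
    right = {0.0: _vertical_wall(20.0)}
    with pytest.raises(ValueError, match="dv=150"):
        brain_width(left, right, [(0.0, 150.0)])


def test_crossing_walls_error():
    left = {0.0: _vertical_wall(20.0)}
    right = {0.0: _vertical_wall(-20.0)}
    with pytest.raises(ValueError, match="cross"):
        brain_width(left, right, [(0.0, 50.0)])


# --- distortion index -------------------------------------------------------


def test_straight_boundary_index_one():
    di = distortion_index(BoundaryPolyline(vertices=[[0, 0], [0, 10]]))
    assert di.index == pytest.approx(1.0)


def test_semicircle_index_pi_over_two():
    theta = np.linspace(-np.pi / 2, np.pi / 2, 2000)
    verts = np.column_stack([5 * np.cos(theta), 5 + 5 * np.sin(theta)])
    di = distortion_index(BoundaryPolyline(vertices=verts))
    assert di.index == pytest.approx(np.pi / 2, abs=1e-3)


def test_staircase_index():
    verts = [[0, 0], [2, 0], [2, 5], [0, 5], [0, 10]]
    di = distortion_index(BoundaryPolyline(vertices=verts))
    assert di.arc_length == pytest.approx(14.0)
    assert di.endpoint_distance == pytest.approx(10.0)
    assert di.index == pytest.approx(1.4)


def test_index_invariant_under_translation_and_ml_reflection(rng):
    dv = np.linspace(0, 60, 80)
    ml = 4 * np.sin(dv / 7) + rng.normal(0, 0.2, dv.size)
    verts = np.column_stack([ml, dv])
    base = distortion_index(BoundaryPolyline(vertices=verts)).index
    shifted = distortion_index(BoundaryPolyline(vertices=verts + [13.0, -7.0])).index
    reflected = distortion_index(
        BoundaryPolyline(vertices=np.column_stack([-ml, dv]))
    ).index
    assert shifted == pytest.approx(base, rel=1e-12)
    assert reflected == pytest.approx(base, rel=1e-12)


def test_index_at_least_one(rng):
    for _ in range(20):
        dv = np.sort(rng.uniform(0, 100, 30))
        dv[0], dv[-1] = 0.0, 100.0
        ml = rng.normal(0, 5, 30)
        di = distortion_index(BoundaryPolyline(vertices=np.column_stack([ml, dv])))
        assert di.index >= 1.0 - 1e-9


def test_coincident_extremes_error():
    with pytest.raises(ValueError, match="coincide"):
        # horizontal boundary: dorsal-most and ventral-most vertices coincide
        distortion_index(BoundaryPolyline(vertices=[[0, 0], [5, 0]]))


# --- interface thickness ----------------------------------------------------


def test_parallel_membranes_ten_samples_mean_equals_gap():
    region = make_interface(gap_px=120.0, region_length_px=1000, px_size_nm=1.0)
    summ = interface_thickness(region, step_px=100)
    assert summ.samples_per_region == (10,)
    assert summ.embryo_mean == pytest.approx(120.0)


@pytest.mark.parametrize("step", [50, 100, 250])
def test_parallel_gap_independent_of_step(step):
    region = make_interface(gap_px=40.0, region_length_px=1000)
    summ = interface_thickness(region, step_px=step)
    assert summ.embryo_mean == pytest.approx(40.0)
    assert summ.samples_per_region == (1000 // step,)


def test_converging_membranes_mean_of_sampled_profile():
    # membrane B drops linearly from 100 to 0 over 1000 px; thickness at
    # station x is the perpendicular distance to the sloped line
    x = np.linspace(0, 1000, 1001)
    a = BoundaryPolyline(vertices=np.column_stack([x, np.zeros_like(x)]))
    b = BoundaryPolyline(vertices=np.column_stack([x, 100.0 - 0.1 * x]))
    from placodetrack.tracks_io import InterfaceRegion

    region = InterfaceRegion(membrane_a=a, membrane_b=b, region_length_px=900, px_size_nm=1.0)
    summ = interface_thickness(region, step_px=100)
    stations = np.arange(1, 10) * 100.0
    vertical = 100.0 - 0.1 * stations
    expected = (vertical / np.sqrt(1 + 0.1**2)).mean()  # point-to-line distance
    assert summ.samples_per_region == (9,)
    assert summ.embryo_mean == pytest.approx(expected, rel=1e-6)


def test_floor_rule_on_950px_region():
    region = make_interface(gap_px=120.0, region_length_px=950)
    summ = interface_thickness(region, step_px=100)
    assert summ.samples_per_region == (9,)


def test_region_shorter_than_step_errors():
    region = make_interface(gap_px=120.0, region_length_px=80)
    with pytest.raises(ValueError, match="shorter"):
        interface_thickness(region, step_px=100)


def test_embryo_mean_averages_region_means():
    assert thickness_embryo_mean([100.0, 140.0]).embryo_mean == pytest.approx(120.0)
    assert thickness_embryo_mean([42.0]).embryo_mean == pytest.approx(42.0)
    assert thickness_embryo_mean([40.0, 40.0, 40.0]).embryo_mean == pytest.approx(40.0)
    region = make_interface(gap_px=120.0, region_length_px=1000)
    summ = interface_thickness(region, step_px=100)
    combined = thickness_embryo_mean([summ, summ])
    assert combined.n_regions == 2
    assert combined.embryo_mean == pytest.approx(120.0)


def test_empty_region_list_errors():
    with pytest.raises(ValueError):
        thickness_embryo_mean([])
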