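"""Motility, adhesion, and fusion metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myoscaffold.motility import (
    AdhesionAssay,
    EllipseRegion,
    FusionField,
    IncompleteTrackError,
    TrackSet,
    adhesion_percent,
    fusion_efficiency,
    interval_speeds,
    mean_speed,
    total_displacement,
)
from myoscaffold.synthetic import (
    FusionFieldTruth,
    TrackTruth,
    generate_fusion_field,
    generate_tracks,
)


def make_tracks(per_cell_xy, interval=10.0):
    rows = []
    for cid, xy in per_cell_xy.items():
        for frame, (x, y) in enumerate(xy):
            rows.append({"cell_id": cid, "frame": frame, "x": x, "y": y})
    return TrackSet(pd.DataFrame(rows), interval)


# ---------------------------------------------------------------------------
# speeds
# ---------------------------------------------------------------------------


def test_stationary_cell_zero_speed():
    ts = make_tracks({0: [(5.0, 5.0)] * 10})
    assert np.allclose(interval_speeds(ts.track(0)), 0.0)


def test_three_four_five_steps():
    xy = [(3.0 * k, 4.0 * k) for k in range(6)]
    ts = make_tracks({0: xy})
    assert np.allclose(interval_speeds(ts.track(0)), 5.0)


def test_gap_yields_no_speed_entry():
    df = pd.DataFrame({
        "cell_id": [0, 0, 0], "frame": [0, 1, 3],
        "x": [0.0, 3.0, 9.0], "y": [0.0, 4.0, 12.0],
    })
    speeds = interval_speeds(TrackSet(df).track(0))
    assert speeds.tolist() == [5.0]  # frame 1 -> 3 is a gap


def test_speeds_need_two_frames():
    ts = make_tracks({0: [(0.0, 0.0)]})
    with pytest.raises(ValueError):
        interval_speeds(ts.track(0))


def test_synthetic_straight_track_mean_speed():
    """Oracle: independent pairwise Euclidean distances."""
    sim = generate_tracks(TrackTruth(n_cells=20, frames=30, speed_mean=6.21,
                                     speed_sd=0.0, persistence=1.0,
                                     dropout_rate=0.0, seed=1))
    summary = mean_speed(sim.tracks)
    assert summary.group_mean == pytest.approx(6.21, abs=1e-9)
    for cid in sim.tracks.cell_ids:
        xy = sim.tracks.track(cid)[["x", "y"]].to_numpy()
        oracle = np.linalg.norm(np.diff(xy, axis=0), axis=1).mean()
        assert oracle == pytest.approx(6.21, abs=1e-9)


def test_group_mean_and_sd():
    ts = make_tracks({
        "a": [(4.0 * k, 0.0) for k in range(5)],
        "b": [(0.0, 6.0 * k) for k in range(5)],
    })
    summary = mean_speed(ts)
    assert summary.group_mean == pytest.approx(5.0)
    assert summary.group_sd == pytest.approx(math.sqrt(2.0))


def test_mean_speed_window_halfopen():
    # speeds at interval starts 0,10,...; window [0, 20) keeps two intervals
    xy = [(0.0, 0.0), (1.0, 0.0), (3.0, 0.0), (6.0, 0.0), (10.0, 0.0)]
    ts = make_tracks({0: xy})
    full = mean_speed(ts).per_cell
    win = mean_speed(ts, (0.0, 20.0)).per_cell
    assert full["mean_speed"][0] == pytest.approx((1 + 2 + 3 + 4) / 4)
    assert win["mean_speed"][0] == pytest.approx((1 + 2) / 2)
    with pytest.raises(ValueError):
        mean_speed(ts, (30.0, 30.0))


def test_window_consistency_mean_between_submeans():
    sim = generate_tracks(TrackTruth(n_cells=6, frames=40, seed=3,
                                     dropout_rate=0.0))
    a = mean_speed(sim.tracks, (0.0, 200.0)).per_cell.set_index("cell_id")
    b = mean_speed(sim.tracks, (200.0, 400.0)).per_cell.set_index("cell_id")
    both = mean_speed(sim.tracks, (0.0, 400.0)).per_cell.set_index("cell_id")
    for cid in both.index:
        lo = min(a.loc[cid, "mean_speed"], b.loc[cid, "mean_speed"])
        hi = max(a.loc[cid, "mean_speed"], b.loc[cid, "mean_speed"])
        assert lo - 1e-12 <= both.loc[cid, "mean_speed"] <= hi + 1e-12


# ---------------------------------------------------------------------------
# displacement
# ---------------------------------------------------------------------------


def test_stationary_displacement_zero():
    ts = make_tracks({0: [(2.0, 2.0)] * 91})
    d = total_displacement(ts, 0)
    assert d.path_length_um == 0.0
    assert d.net_displacement_um == 0.0
    assert d.n_intervals == 90


def test_constant_speed_15h_path():
    ts = make_tracks({0: [(5.0 * k, 0.0) for k in range(91)]})
    d = total_displacement(ts, 0)
    assert d.path_length_um == pytest.approx(450.0)


def test_path_length_at_least_net_displacement():
    """Triangle inequality on random-walk tracks."""
    sim = generate_tracks(TrackTruth(n_cells=10, frames=91, persistence=0.3,
                                     dropout_rate=0.0, seed=5))
    for cid in sim.tracks.cell_ids:
        d = total_displacement(sim.tracks, cid)
        assert d.path_length_um >= d.net_displacement_um - 1e-9


def test_incomplete_track_structured_exclusion():
    xy = [(float(k), 0.0) for k in range(50)]  # only 50 of 91 frames
    ts = make_tracks({0: xy})
    with pytest.raises(IncompleteTrackError) as exc:
        total_displacement(ts, 0)
    assert exc.value.cell_id == 0
    assert 50 in exc.value.missing_frames


# ---------------------------------------------------------------------------
# rigid-motion invariance
# ---------------------------------------------------------------------------


@settings(derandomize=True, max_examples=20, deadline=None)
@given(angle=st.floats(min_value=-math.pi, max_value=math.pi),
       dx=st.floats(min_value=-500, max_value=500),
       dy=st.floats(min_value=-500, max_value=500))
def test_rigid_motion_invariance(angle, dx, dy):
    sim = generate_tracks(TrackTruth(n_cells=4, frames=20, seed=6,
                                     dropout_rate=0.0))
    moved = sim.tracks.transformed(angle_rad=angle, dx=dx, dy=dy)
    base = mean_speed(sim.tracks)
    got = mean_speed(moved)
    assert got.group_mean == pytest.approx(base.group_mean, abs=1e-9)
    assert got.group_sd == pytest.approx(base.group_sd, abs=1e-9)
    for cid in sim.tracks.cell_ids:
        d0 = total_displacement(sim.tracks, cid, 190.0)
        d1 = total_displacement(moved, cid, 190.0)
        assert d1.path_length_um == pytest.approx(d0.path_length_um, abs=1e-9)
        assert d1.net_displacement_um == pytest.approx(
            d0.net_displacement_um, abs=1e-9)


# ---------------------------------------------------------------------------
# adhesion
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("pre,post,expected", [
    (100, 25, 25.0),
    (100, 2, 2.0),
    (200, 128, 64.0),
])
def test_adhesion_percent(pre, post, expected):
    assert adhesion_percent(AdhesionAssay(pre, post)) == pytest.approx(expected)


def test_adhesion_zero_pre_count_errors_and_excess_warns():
    with pytest.raises(ValueError):
        adhesion_percent(AdhesionAssay(0, 0))
    with pytest.warns(UserWarning):
        adhesion_percent(AdhesionAssay(10, 12))


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------


def test_fusion_simple_counts():
    region = EllipseRegion(10.0, 10.0, 5.0, 3.0, label=1)
    inside = [(10.0, 10.0), (12.0, 10.0), (8.0, 11.0)]
    free = [(50.0 + i, 50.0) for i in range(7)]
    res = fusion_efficiency(FusionField(np.array(inside + free), (region,)))
    assert res.efficiency_percent == pytest.approx(30.0)
    assert res.region_table.iloc[0]["classification"] == "myotube"


def test_two_nucleus_region_is_myocyte():
    region = EllipseRegion(10.0, 10.0, 5.0, 3.0, label=1)
    nuclei = [(10.0, 10.0), (11.0, 10.0)] + [(60.0 + i, 60.0) for i in range(8)]
    res = fusion_efficiency(FusionField(np.array(nuclei), (region,)))
    assert res.efficiency_percent == 0.0
    assert res.region_table.iloc[0]["classification"] == "myocyte"


def test_three_nucleus_boundary_is_myotube():
    region = EllipseRegion(10.0, 10.0, 5.0, 3.0, label=1)
    nuclei = [(9.0, 10.0), (10.0, 10.0), (11.0, 10.0), (60.0, 60.0)]
    res = fusion_efficiency(FusionField(np.array(nuclei), (region,)))
    assert res.efficiency_percent == pytest.approx(75.0)


def test_boundary_nucleus_counts_as_inside():
    region = EllipseRegion(10.0, 10.0, 5.0, 3.0, label=1)
    nuclei = [(15.0, 10.0), (10.0, 13.0), (5.0, 10.0)]  # all exactly on edge
    res = fusion_efficiency(FusionField(np.array(nuclei), (region,)))
    assert res.efficiency_percent == pytest.approx(100.0)


def test_fusion_monotone_in_membership():
    """Adding a myotube nucleus raises the index; adding a free nucleus
    lowers it."""
    region = EllipseRegion(10.0, 10.0, 5.0, 3.0, label=1)
    base_nuclei = [(10.0, 10.0), (11.0, 10.0), (9.0, 10.0), (60.0, 60.0)]
    base = fusion_efficiency(FusionField(np.array(base_nuclei), (region,)))
    plus_tube = fusion_efficiency(FusionField(
        np.array(base_nuclei + [(10.0, 11.0)]), (region,)))
    plus_free = fusion_efficiency(FusionField(
        np.array(base_nuclei + [(70.0, 70.0)]), (region,)))
    assert plus_tube.efficiency_percent > base.efficiency_percent
    assert plus_free.efficiency_percent < base.efficiency_percent


def test_fusion_empty_field_errors():
    with pytest.raises(ValueError):
        fusion_efficiency(FusionField(np.empty((0, 2)), ()))


def test_pipeline_equals_generator_truth():
    """Point-in-region oracle recomputed independently per nucleus."""
    for seed in range(10):
        sim = generate_fusion_field(FusionFieldTruth(seed=seed))
        res = fusion_efficiency(sim.field)
        assert res.efficiency_percent == pytest.approx(
            sim.true_index_percent, abs=1e-12)
        # independent membership check
        n_in = 0
        myotube_labels = {
            lbl for lbl, cnt in sim.nuclei_per_region.items() if cnt >= 3
        }
        for x, y in sim.field.nuclei:
            for r in sim.field.regions:
                if ((x - r.cx) / r.semi_x) ** 2 + ((y - r.cy) / r.semi_y) ** 2 <= 1:
                    if r.label in myotube_labels:
                        n_in += 1
                    break
        assert res.efficiency_percent == pytest.approx(
            100.0 * n_in / len(sim.field.nuclei))
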