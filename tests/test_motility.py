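"""Motion parameters: closed-form values, windowing, migration classification."""

import logging
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chiptrack import SimulationConfig, simulate_tracks
from chiptrack.motility import (
    WindowSpec,
    annotate_regions,
    classify_migration,
    count_by_window,
    directional_persistence,
    displacement,
    fold_increase,
    path_length,
    speed,
    window_metrics,
)


def track_df(points, frame_interval_frames=1, cls="dc", tid=0, start_frame=0):
    frames = [start_frame + i * frame_interval_frames for i in range(len(points))]
    return pd.DataFrame(
        {
            "track_id": tid,
            "class": cls,
            "frame": frames,
            "x_um": [p[0] for p in points],
            "y_um": [p[1] for p in points],
            "det_id": range(len(points)),
            "interpolated": False,
        }
    )


PATH_345 = np.array([[0.0, 0.0], [3.0, 0.0], [3.0, 4.0]])


class TestClosedFormMetrics:
    def test_path_length_3_4_5(self):
        assert path_length(PATH_345) == pytest.approx(7.0)

    def test_single_point_missing(self):
        assert math.isnan(path_length(np.array([[1.0, 1.0]])))
        assert math.isnan(displacement(np.array([[1.0, 1.0]])))

    def test_random_walk_equals_stepwise_accumulation(self):
        rng = np.random.default_rng(0)
        xy = rng.normal(0, 5, (101, 2)).cumsum(axis=0)
        acc = sum(
            math.hypot(xy[i + 1, 0] - xy[i, 0], xy[i + 1, 1] - xy[i, 1])
            for i in range(100)
        )
        assert path_length(xy) == pytest.approx(acc)

    def test_dp_of_3_4_5_path(self):
        assert directional_persistence(PATH_345) == pytest.approx(5.0 / 7.0)

    def test_dp_extremes(self):
        straight = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        assert directional_persistence(straight) == pytest.approx(1.0)
        loop = np.array([[0.0, 0.0], [5.0, 5.0], [0.0, 0.0]])
        assert directional_persistence(loop) == pytest.approx(0.0)

    def test_displacement_modes(self):
        xy = np.array([[0.0, 0.0], [300.0, 400.0]])
        assert displacement(xy, "euclidean") == pytest.approx(500.0)
        assert displacement(xy, "horizontal") == pytest.approx(300.0)

    def test_collinear_axial_track_all_equal(self):
        xy = np.array([[0.0, 5.0], [10.0, 5.0], [25.0, 5.0]])
        assert (
            path_length(xy)
            == pytest.approx(displacement(xy, "euclidean"))
            == pytest.approx(displacement(xy, "horizontal"))
        )
        assert directional_persistence(xy) == pytest.approx(1.0)

    def test_speed_ratio(self):
        xy = np.array([[0.0, 0.0], [10.0, 0.0]])
        assert speed(xy, 5.0) == pytest.approx(2.0)
        assert math.isnan(speed(xy, 0.0))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 40))
    def test_dp_bounds_and_triangle_inequality(self, seed, n):
        rng = np.random.default_rng(seed)
        xy = rng.normal(0, 3, (n, 2)).cumsum(axis=0)
        pl = path_length(xy)
        d = displacement(xy, "euclidean")
        assert pl + 1e-9 >= d
        dp = directional_persistence(xy)
        if not math.isnan(dp):
            assert 0.0 <= dp <= 1.0


class TestMigrationClassification:
    def test_confined_track_not_migrating(self, layout2):
        cx, cy = layout2.immune_chamber.center
        tr = annotate_regions(track_df([(cx, cy), (cx + 5, cy)]), layout2)
        status = classify_migration(tr)
        assert status == {
            "migrated": False,
            "infiltrated": False,
            "first_entry_frame": None,
            "first_infiltration_frame": None,
            "side": None,
            "reverse_crossing": False,
        }

    def test_mid_channel_track_migrated_not_infiltrated(self, layout2):
        ch = layout2.connecting_channels["right"][0]
        mx, my = ch.center
        tr = annotate_regions(
            track_df([(layout2.immune_chamber.x1 - 10, my), (mx, my)]), layout2
        )
        status = classify_migration(tr)
        assert status["migrated"] and not status["infiltrated"]
        assert status["side"] == "right"
        assert status["first_entry_frame"] == 1

    def test_straight_crossing_infiltrates(self, layout2):
        ch = layout2.connecting_channels["right"][0]
        my = ch.center[1]
        xs = np.linspace(layout2.immune_chamber.x1 - 50, ch.x1 + 50, 11)
        tr = annotate_regions(track_df([(x, my) for x in xs]), layout2)
        status = classify_migration(tr)
        assert status["migrated"] and status["infiltrated"]
        assert status["first_entry_frame"] <= status["first_infiltration_frame"]

    def test_reverse_crossing_flagged(self, layout2):
        ch = layout2.connecting_channels["right"][0]
        my = ch.center[1]
        tumor_x = ch.x1 + 30
        tr = annotate_regions(
            track_df([(ch.x0 - 10, my), (ch.center[0], my), (tumor_x, my),
                      (ch.center[0], my)]),
            layout2,
        )
        assert classify_migration(tr)["reverse_crossing"]

    def test_migrated_contains_infiltrated_on_cohort(self, layout2):
        cfg = SimulationConfig(n_dcs=80, n_cancer_per_chamber=0, n_frames=100,
                               bias_strength=0.6, seed=17)
        rows = []
        for tr in simulate_tracks(cfg, layout2):
            for f, (x, y) in zip(tr.frames(), tr.positions):
                rows.append((tr.agent_id, "dc", int(f), x, y, -1, False))
        tracks = annotate_regions(
            pd.DataFrame(
                rows,
                columns=["track_id", "class", "frame", "x_um", "y_um", "det_id",
                         "interpolated"],
            ),
            layout2,
        )
        windows = WindowSpec(windows=((0.0, 2.0), (2.0, 4.0)), min_frames_in_window=2)
        counts = count_by_window(tracks, windows, frame_interval=2.0)
        for _, row in counts.iterrows():
            assert row["migrating"] >= row["infiltrated"]
        assert counts["migrating"].sum() > 0


class TestWindows:
    def test_event_window_assignment(self, layout2):
        windows = WindowSpec()
        assert windows.window_of(30.0) == 1
        assert windows.window_of(24.0) == 1  # boundary: half-open
        assert windows.window_of(23.999) == 0
        assert windows.window_of(80.0) is None

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(windows=((0.0, 24.0), (12.0, 36.0)))

    def test_infiltration_counted_in_event_window_only(self, layout2):
        ch = layout2.connecting_channels["right"][0]
        my = ch.center[1]
        # 2-min frames: infiltration at frame 900 = 30 h -> window 24-48 h
        pts = [(layout2.immune_chamber.x1 - 20, my)] * 899 + [(ch.x1 + 30, my)] * 10
        tracks = annotate_regions(track_df(pts), layout2)
        counts = count_by_window(tracks, WindowSpec(), frame_interval=2.0)
        counts = counts.set_index(["side", "window"])
        assert counts.loc[("right", "24-48h"), "infiltrated"] == 1
        assert counts.loc[("right", "0-24h"), "infiltrated"] == 0
        # migration (channel entry at the same frame) in the same window
        assert counts.loc[("right", "24-48h"), "migrating"] == 1

    def test_track_spanning_two_windows_two_rows(self, layout2):
        cx, cy = layout2.immune_chamber.center
        # 2-min frames; 1500 frames = 50 h straight run (tiny steps)
        pts = [(cx - 150 + 0.2 * i, cy) for i in range(1500)]
        tracks = annotate_regions(track_df(pts), layout2)
        met = window_metrics(tracks, WindowSpec(), 2.0)
        assert set(met["window"]) == {"0-24h", "24-48h", "48-72h"}
        assert (met["dp"] > 0.999).all()

    def test_min_frames_filter(self, layout2):
        cx, cy = layout2.immune_chamber.center
        tracks = annotate_regions(track_df([(cx + i, cy) for i in range(3)]), layout2)
        met = window_metrics(tracks, WindowSpec(min_frames_in_window=5), 2.0)
        assert len(met) == 0

    def test_pre_and_post_channel_speeds(self, layout2):
        ch = layout2.connecting_channels["right"][0]
        my = ch.center[1]
        imm_x1 = layout2.immune_chamber.x1
        # 10 µm/frame in immune (5 µm/min at 2-min frames), cross the
        # channel, then 4 µm/frame (2 µm/min) in the tumor chamber
        pts = [(imm_x1 - 100 + 10 * i, my) for i in range(10)]  # immune approach
        x = pts[-1][0]
        while x < ch.x1 + 2:
            x += 10
            pts.append((x, my))
        pts += [(pts[-1][0] + 4 * (i + 1), my) for i in range(10)]
        tracks = annotate_regions(track_df(pts), layout2)
        met = window_metrics(tracks, WindowSpec(min_frames_in_window=2), 2.0)
        assert len(met) == 1
        row = met.iloc[0]
        assert row["pre_channel_speed_um_min"] == pytest.approx(5.0, rel=1e-6)
        assert row["post_channel_speed_um_min"] == pytest.approx(2.0, rel=1e-6)
        assert row["side"] == "right"

    def test_track_never_in_tumor_post_speed_missing(self, layout2):
        cx, cy = layout2.immune_chamber.center
        tracks = annotate_regions(
            track_df([(cx + 2 * i, cy) for i in range(10)]), layout2
        )
        met = window_metrics(tracks, WindowSpec(min_frames_in_window=2), 2.0)
        assert math.isnan(met["post_channel_speed_um_min"].iloc[0])


class TestCohortStatistics:
    @pytest.mark.parametrize("speed_mean", [2.0, 5.0, 8.0])
    def test_speed_recovered_through_metric(self, layout2, speed_mean):
        cfg = SimulationConfig(
            n_dcs=200, n_cancer_per_chamber=0, n_frames=100, speed_mean=speed_mean,
            speed_sd=0.3 * speed_mean, bias_strength=0.0, seed=31,
        )
        speeds = []
        for tr in simulate_tracks(cfg, layout2):
            duration = (len(tr.positions) - 1) * cfg.frame_interval
            speeds.append(speed(tr.positions, duration))
        speeds = np.array(speeds)
        se = speeds.std(ddof=1) / np.sqrt(len(speeds))
        assert abs(speeds.mean() - speed_mean) <= 3 * se

    def test_dp_strictly_increases_with_bias(self, layout2):
        means = []
        for b in (0.0, 0.5, 1.0):
            cfg = SimulationConfig(
                n_dcs=200, n_cancer_per_chamber=0, n_frames=60,
                bias_strength=b, persistence=2.0, seed=23,
            )
            dp = [directional_persistence(t.positions)
                  for t in simulate_tracks(cfg, layout2)]
            means.append(np.nanmean(dp))
        assert means[0] < means[1] < means[2]


class TestFoldIncrease:
    def test_ratio(self):
        assert fold_increase(30, 6) == pytest.approx(5.0)
        assert fold_increase(7, 7) == pytest.approx(1.0)

    def test_zero_control_missing(self, caplog):
        with caplog.at_level(logging.WARNING, logger="chiptrack.motility"):
            assert math.isnan(fold_increase(10, 0))
        assert "control" in caplog.text

    def test_bias_on_vs_off_ordering(self, layout2):
        counts = {}
        for b in (0.0, 0.8):
            cfg = SimulationConfig(n_dcs=150, n_cancer_per_chamber=0, n_frames=120,
                                   bias_strength=b, seed=19)
            rows = []
            for tr in simulate_tracks(cfg, layout2):
                for f, (x, y) in zip(tr.frames(), tr.positions):
                    rows.append((tr.agent_id, "dc", int(f), x, y, -1, False))
            tracks = annotate_regions(
                pd.DataFrame(rows, columns=["track_id", "class", "frame", "x_um",
                                            "y_um", "det_id", "interpolated"]),
                layout2,
            )
            windows = WindowSpec(windows=((0.0, 4.0),), min_frames_in_window=2)
            c = count_by_window(tracks, windows, 2.0).set_index(["side", "window"])
            counts[b] = c.loc[("right", "0-4h"), "infiltrated"]
        assert counts[0.0] > 0
        assert fold_increase(counts[0.8], counts[0.0]) > 1.0
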