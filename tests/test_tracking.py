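"""Linking: optimal assignment vs brute force, gating, gap closing."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chiptrack.tracking import (
    LinkParams,
    assignment_cost,
    close_gaps,
    link_frames,
    track_stack,
)


def brute_force_cost(prev_xy, next_xy, gate):
    """Exhaustive minimum of the gated assignment objective.

    Enumerates every one-to-one partial matching with links within the gate;
    objective = sum of squared link displacements + gate^2 per unmatched
    point on either side.
    """
    n, m = len(prev_xy), len(next_xy)
    d2 = ((prev_xy[:, None, :] - next_xy[None, :, :]) ** 2).sum(axis=2)
    best = float("inf")
    best_links = []
    for k in range(min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                if any(d2[r, c] > gate**2 for r, c in zip(rows, cols)):
                    continue
                cost = sum(d2[r, c] for r, c in zip(rows, cols))
                cost += gate**2 * ((n - k) + (m - k))
                if cost < best - 1e-12:
                    best = cost
                    best_links = sorted(zip(rows, cols))
    return best, best_links


def detections_frame(points, frame, start_id=0, cls="dc"):
    return pd.DataFrame(
        {
            "det_id": np.arange(start_id, start_id + len(points)),
            "frame": frame,
            "class": cls,
            "x_um": [p[0] for p in points],
            "y_um": [p[1] for p in points],
        }
    )


class TestAssignment:
    def test_three_vs_three_matches_permutation_minimum(self):
        prev_xy = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        next_xy = np.array([[1.0, 1.0], [11.0, 1.0], [1.0, 9.0]])
        links, cost = assignment_cost(prev_xy, next_xy, gate=50.0)
        oracle_cost, oracle_links = brute_force_cost(prev_xy, next_xy, 50.0)
        assert links == oracle_links == [(0, 0), (1, 1), (2, 2)]
        assert cost == pytest.approx(oracle_cost)

    def test_random_instances_match_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = rng.integers(0, 8)
            m = rng.integers(0, 8)
            prev_xy = rng.uniform(0, 100, (n, 2))
            next_xy = rng.uniform(0, 100, (m, 2))
            gate = rng.uniform(10, 80)
            _, cost = assignment_cost(prev_xy, next_xy, gate)
            oracle_cost, _ = brute_force_cost(prev_xy, next_xy, gate)
            assert cost == pytest.approx(oracle_cost), (n, m, gate)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_assignment_matches_brute_force_property(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(0, 6, 2)
        prev_xy = rng.uniform(0, 60, (n, 2))
        next_xy = rng.uniform(0, 60, (m, 2))
        _, cost = assignment_cost(prev_xy, next_xy, 30.0)
        oracle_cost, _ = brute_force_cost(prev_xy, next_xy, 30.0)
        assert cost == pytest.approx(oracle_cost)

    def test_empty_sides(self):
        links, cost = assignment_cost(np.zeros((0, 2)), np.ones((3, 2)), 10.0)
        assert links == [] and cost == pytest.approx(300.0)


class TestLinkFrames:
    def test_single_detection_chain(self):
        det = pd.concat(
            [detections_frame([(0, 0)], 0), detections_frame([(5, 0)], 1, 1)]
        )
        tracks = link_frames(det, LinkParams(gate_distance=10))
        assert tracks["track_id"].nunique() == 1
        assert len(tracks) == 2

    def test_gate_violation_opens_new_tracks(self):
        # two detections swap positions by a jump farther than the gate
        det = pd.concat(
            [
                detections_frame([(0.0, 0.0), (100.0, 0.0)], 0),
                detections_frame([(100.0, 0.0), (0.0, 0.0)], 1, 2),
            ]
        )
        tracks = link_frames(det, LinkParams(gate_distance=30))
        # staying in place is within the gate, so identity links are chosen
        assert tracks["track_id"].nunique() == 2
        for _, tr in tracks.groupby("track_id"):
            xs = tr["x_um"].to_numpy()
            assert xs[0] == xs[-1]

    def test_true_swap_terminates_both(self):
        det = pd.concat(
            [
                detections_frame([(0.0, 0.0), (100.0, 0.0)], 0),
                detections_frame([(40.0, 0.0), (140.0, 0.0)], 1, 2),
            ]
        )
        tracks = link_frames(det, LinkParams(gate_distance=30))
        assert tracks["track_id"].nunique() == 4


class TestCloseGaps:
    def test_single_dropout_interpolated(self):
        det = pd.concat(
            [
                detections_frame([(0.0, 0.0)], 0, 0),
                detections_frame([(20.0, 0.0)], 2, 1),
                detections_frame([(30.0, 0.0)], 3, 2),
            ]
        )
        params = LinkParams(gate_distance=15, gap_frames=2, min_track_length=1)
        tracks = track_stack(det, params)
        assert tracks["track_id"].nunique() == 1
        interp = tracks[tracks["interpolated"]]
        assert len(interp) == 1
        assert interp["frame"].iloc[0] == 1
        assert interp["x_um"].iloc[0] == pytest.approx(10.0)  # midpoint
        assert interp["y_um"].iloc[0] == pytest.approx(0.0)

    def test_no_candidates_unchanged(self):
        det = pd.concat(
            [detections_frame([(0.0, 0.0)], 0, 0), detections_frame([(500.0, 0.0)], 2, 1)]
        )
        linked = link_frames(det, LinkParams())
        merged = close_gaps(linked, LinkParams(gate_distance=15, gap_frames=2))
        pd.testing.assert_frame_equal(merged, linked)

    def test_lower_cost_continuation_wins(self):
        # one track end at (0,0)@1; two later starts at distance 5 and 10
        det = pd.concat(
            [
                detections_frame([(0.0, 0.0)], 0, 0),
                detections_frame([(0.0, 0.0)], 1, 1),
                detections_frame([(5.0, 0.0), (10.0, 0.0)], 3, 2),
                detections_frame([(5.0, 0.0), (10.0, 0.0)], 4, 4),
            ]
        )
        params = LinkParams(gate_distance=4.0, gap_frames=2, min_track_length=1)
        tracks = track_stack(det, params)
        merged = tracks.groupby("track_id")["frame"].agg(["min", "max"])
        spanning = merged[(merged["min"] == 0) & (merged["max"] == 4)]
        assert len(spanning) == 1
        tid = spanning.index[0]
        tr = tracks[tracks["track_id"] == tid].sort_values("frame")
        assert tr[~tr["interpolated"]]["x_um"].iloc[-1] == pytest.approx(5.0)
        assert tracks["track_id"].nunique() == 2  # the other start stays separate


class TestTrackStack:
    def test_min_track_length_filters_everything(self):
        det = pd.concat([detections_frame([(0, 0)], f, f) for f in range(4)])
        tracks = track_stack(det, LinkParams(min_track_length=5))
        assert len(tracks) == 0

    def test_detection_used_at_most_once(self, layout2):
        rng = np.random.default_rng(3)
        frames = []
        start = 0
        for f in range(10):
            pts = rng.uniform(100, 900, (12, 2))
            frames.append(detections_frame([tuple(p) for p in pts], f, start))
            start += 12
        det = pd.concat(frames)
        tracks = track_stack(det, LinkParams(gate_distance=200, min_track_length=1))
        real = tracks[tracks["det_id"] >= 0]
        assert real["det_id"].is_unique

    def test_no_link_exceeds_gate(self):
        rng = np.random.default_rng(4)
        frames = []
        start = 0
        for f in range(8):
            pts = rng.uniform(0, 300, (8, 2))
            frames.append(detections_frame([tuple(p) for p in pts], f, start))
            start += 8
        params = LinkParams(gate_distance=60, gap_frames=2, min_track_length=1)
        det = pd.concat(frames)
        tracks = track_stack(det, params)
        for _, tr in tracks.groupby("track_id"):
            tr = tr.sort_values("frame")
            xy = tr[["x_um", "y_um"]].to_numpy()
            fr = tr["frame"].to_numpy()
            steps = np.hypot(*np.diff(xy, axis=0).T)
            gaps = np.diff(fr)
            assert (steps <= params.gate_distance * gaps + 1e-9).all()

    def test_recovers_simulated_tracks_from_truth_detections(self, layout2):
        """Noiseless truth positions re-linked with >= 99% per-link accuracy."""
        from chiptrack import SimulationConfig, simulate_tracks

        cfg = SimulationConfig(n_dcs=30, n_cancer_per_chamber=0, n_frames=40,
                               speed_mean=5.0, seed=14)
        truth = simulate_tracks(cfg, layout2)
        rows = []
        det_id = 0
        for tr in truth:
            for f, (x, y) in zip(tr.frames(), tr.positions):
                rows.append((det_id, int(f), "dc", x, y, tr.agent_id))
                det_id += 1
        det = pd.DataFrame(rows, columns=["det_id", "frame", "class", "x_um", "y_um", "agent"])
        params = LinkParams(gate_distance=3 * 5.0 * 2.0, gap_frames=0, min_track_length=2)
        tracks = track_stack(det, params)
        merged = tracks.merge(det[["det_id", "agent"]], on="det_id")
        good = total = 0
        for _, tr in merged.sort_values("frame").groupby("track_id"):
            ag = tr["agent"].to_numpy()
            good += (ag[1:] == ag[:-1]).sum()
            total += len(ag) - 1
        assert total > 0
        assert good / total >= 0.99

    def test_cancer_jitter_one_track_per_cell(self, layout2):
        from chiptrack import SimulationConfig, simulate_tracks

        cfg = SimulationConfig(n_dcs=0, n_cancer_per_chamber=8, n_frames=30, seed=2)
        truth = simulate_tracks(cfg, layout2)
        rows = []
        det_id = 0
        for tr in truth:
            for f, (x, y) in zip(tr.frames(), tr.positions):
                rows.append((det_id, int(f), "cancer", x, y))
                det_id += 1
        det = pd.DataFrame(rows, columns=["det_id", "frame", "class", "x_um", "y_um"])
        tracks = track_stack(det, LinkParams(gate_distance=10, min_track_length=5))
        assert tracks["track_id"].nunique() == 16  # 8 per chamber
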