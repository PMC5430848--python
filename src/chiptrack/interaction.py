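"""Immune-cell / cancer-cell contact events and dwell times.

A contact is scored whenever a motile immune cell's centroid lies within a
circular region of interaction of radius ``radius`` around a cancer cell's
centroid, inside a tumor chamber. Maximal runs of in-radius frames form
events; runs separated by at most ``gap_tolerance`` frames (single missed
detections) are merged. Event duration counts both endpoints:
``(end - start + 1) * frame_interval`` minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .motility import WindowSpec

__all__ = ["detect_interactions", "mean_interaction_time", "EVENT_COLUMNS"]

EVENT_COLUMNS = [
    "dc_track_id",
    "cancer_track_id",
    "side",
    "start_frame",
    "end_frame",
    "duration_min",
]


def _runs(frames: np.ndarray, gap_tolerance: int) -> list[tuple[int, int]]:
    """Maximal runs over sorted frame indices, merging gaps <= gap_tolerance."""
    if len(frames) == 0:
        return []
    runs = []
    start = prev = int(frames[0])
    for f in frames[1:]:
        f = int(f)
        if f - prev > gap_tolerance + 1:
            runs.append((start, prev))
            start = f
        prev = f
    runs.append((start, prev))
    return runs


def detect_interactions(
    dc_tracks: pd.DataFrame,
    cancer_tracks: pd.DataFrame,
    radius: float,
    frame_interval: float,
    gap_tolerance: int = 1,
) -> pd.DataFrame:
    """Detect dwell events between every (immune, cancer) track pair.

    Both track tables must be region-annotated and share the frame clock.
    An immune cell inside two interaction regions at once yields one event
    per cancer cell. Returns the events table (:data:`EVENT_COLUMNS`).
    """
    if radius <= 0:
        raise ValueError("interaction radius must be > 0")
    events = []
    if len(dc_tracks) and len(cancer_tracks):
        # frame x track position matrices; NaN where a track has no point
        dx = dc_tracks.pivot(index="frame", columns="track_id", values="x_um")
        dy = dc_tracks.pivot(index="frame", columns="track_id", values="y_um")
        side_code = (
            dc_tracks.assign(
                _side=dc_tracks["region"].map(
                    lambda r: 1 if r == "tumor_left" else (2 if r == "tumor_right" else 0)
                )
            ).pivot(index="frame", columns="track_id", values="_side")
        ).fillna(0)
        frames_idx = dx.index.to_numpy()
        dc_ids = dx.columns.to_numpy()
        X = dx.to_numpy(float)
        Y = dy.to_numpy(float)
        S = side_code.to_numpy()
        for ca_id, ca in cancer_tracks.groupby("track_id"):
            ca = ca.set_index("frame").reindex(frames_idx)
            cx = ca["x_um"].to_numpy(float)[:, None]
            cy = ca["y_um"].to_numpy(float)[:, None]
            with np.errstate(invalid="ignore"):
                ok = (np.hypot(X - cx, Y - cy) <= radius) & (S > 0)
            for j in np.flatnonzero(ok.any(axis=0)):
                frames = frames_idx[ok[:, j]]
                for start, end in _runs(np.sort(frames), gap_tolerance):
                    row = np.searchsorted(frames_idx, start)
                    side = "left" if S[row, j] == 1 else "right"
                    events.append(
                        {
                            "dc_track_id": int(dc_ids[j]),
                            "cancer_track_id": int(ca_id),
                            "side": side,
                            "start_frame": int(start),
                            "end_frame": int(end),
                            "duration_min": (int(end) - int(start) + 1) * frame_interval,
                        }
                    )
    out = pd.DataFrame(events, columns=EVENT_COLUMNS)
    return out.sort_values(["dc_track_id", "cancer_track_id", "start_frame"]).reset_index(
        drop=True
    )


def mean_interaction_time(
    events: pd.DataFrame,
    windows: WindowSpec,
    frame_interval: float,
) -> pd.DataFrame:
    """Per-side, per-window mean event duration (min) with dispersion.

    Events are assigned to windows by start frame. Windows without events
    report n = 0 and missing mean/sd.
    """
    rows = []
    for side in ("left", "right"):
        for w in range(len(windows.windows)):
            label = windows.label(w)
            sel = events[
                (events["side"] == side)
                & (
                    events["start_frame"].apply(
                        lambda f: windows.window_of(f * frame_interval / 60.0)
                    )
                    == w
                )
            ] if len(events) else events
            durations = sel["duration_min"].to_numpy() if len(sel) else np.array([])
            rows.append(
                {
                    "side": side,
                    "window": label,
                    "n": len(durations),
                    "mean_min": float(durations.mean()) if len(durations) else float("nan"),
                    "sd_min": float(durations.std(ddof=1)) if len(durations) > 1 else float("nan"),
                }
            )
    return pd.DataFrame(rows)
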