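"""Per-track motion parameters and compartment-aware migration read-outs.

Implements the standard single-cell motility statistics for the co-culture
chip, per track and per time window:

* path length — sum of consecutive Euclidean steps (µm);
* speed — path length / duration (µm/min), with pre-channel (immune chamber
  before first channel entry) and post-channel (tumor chamber after first
  infiltration) variants;
* displacement — start-to-end distance, Euclidean or horizontal (|Δx| along
  the immune→tumor axis);
* directional persistence (DP) — Euclidean displacement / path length,
  in [0, 1]: 1 for a straight monotone path, near 0 for Brownian wandering;
* migration classification — a track is *migrating* once it reaches a
  connecting channel or tumor chamber, *infiltrated* once it reaches a tumor
  chamber; counts are tallied per side and per time window by event frame.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import REGION_LABELS, DeviceLayout, classify_points

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "path_length",
    "speed",
    "displacement",
    "directional_persistence",
    "annotate_regions",
    "classify_migration",
    "count_by_window",
    "fold_increase",
    "window_metrics",
    "METRIC_COLUMNS",
]

MIGRATING_REGIONS = {"channel_left", "channel_right", "tumor_left", "tumor_right"}
TUMOR_REGIONS = {"tumor_left", "tumor_right"}

METRIC_COLUMNS = [
    "track_id",
    "window",
    "side",
    "n_points",
    "path_length_um",
    "displacement_euclidean_um",
    "displacement_horizontal_um",
    "dp",
    "speed_um_min",
    "pre_channel_speed_um_min",
    "post_channel_speed_um_min",
    "migrated",
    "infiltrated",
]


@dataclass(frozen=True)
class WindowSpec:
    """Half-open analysis windows in hours; default 0-24, 24-48, 48-72 h."""

    windows: tuple[tuple[float, float], ...] = ((0.0, 24.0), (24.0, 48.0), (48.0, 72.0))
    min_frames_in_window: int = 5

    def __post_init__(self) -> None:
        prev_end = -math.inf
        for start, end in self.windows:
            if not (start < end and start >= prev_end):
                raise ValueError("windows must be increasing and non-overlapping")
            prev_end = end

    def label(self, idx: int) -> str:
        s, e = self.windows[idx]
        return f"{s:g}-{e:g}h"

    def window_of(self, hours: float) -> int | None:
        for i, (s, e) in enumerate(self.windows):
            if s <= hours < e:
                return i
        return None


# ---------------------------------------------------------------------------
# per-segment primitives


def path_length(xy: np.ndarray) -> float:
    """Total distance travelled along a (n, 2) µm polyline; NaN if n < 2."""
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 2:
        return float("nan")
    return float(np.hypot(*np.diff(xy, axis=0).T).sum())


def displacement(xy: np.ndarray, mode: str = "euclidean") -> float:
    """Start-to-end displacement; 'horizontal' takes |Δx| only."""
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 2:
        return float("nan")
    d = xy[-1] - xy[0]
    if mode == "euclidean":
        return float(np.hypot(*d))
    if mode == "horizontal":
        return float(abs(d[0]))
    raise ValueError("mode must be 'euclidean' or 'horizontal'")


def directional_persistence(xy: np.ndarray) -> float:
    """Euclidean displacement over path length, in [0, 1]; NaN if path = 0."""
    pl = path_length(xy)
    if not pl > 0:
        return float("nan")
    return float(min(displacement(xy, "euclidean") / pl, 1.0))


def speed(xy: np.ndarray, duration_min: float) -> float:
    """Mean speed = path length / duration (µm/min); NaN if degenerate."""
    if duration_min <= 0:
        return float("nan")
    pl = path_length(xy)
    return float(pl / duration_min) if pl == pl else float("nan")


# ---------------------------------------------------------------------------
# region annotation and migration classification


def annotate_regions(tracks: pd.DataFrame, layout: DeviceLayout) -> pd.DataFrame:
    """Add a 'region' column by classifying each track point in the layout."""
    out = tracks.copy()
    codes = classify_points(layout, out["x_um"].to_numpy(), out["y_um"].to_numpy())
    out["region"] = [REGION_LABELS[c] for c in codes]
    return out


def _side_of(region: str) -> str | None:
    if region.endswith("_left"):
        return "left"
    if region.endswith("_right"):
        return "right"
    return None


def classify_migration(track: pd.DataFrame) -> dict:
    """Migration status of one region-annotated track.

    Returns migrated/infiltrated flags, the frames of first channel-or-tumor
    entry and first tumor entry, the side of migration (side of the first
    compartment entered) and a reverse-crossing flag (back into a channel
    after infiltration).
    """
    track = track.sort_values("frame")
    regions = track["region"].to_numpy()
    frames = track["frame"].to_numpy()
    mig_mask = np.isin(regions, list(MIGRATING_REGIONS))
    inf_mask = np.isin(regions, list(TUMOR_REGIONS))
    migrated = bool(mig_mask.any())
    infiltrated = bool(inf_mask.any())
    first_entry = int(frames[mig_mask][0]) if migrated else None
    first_infiltration = int(frames[inf_mask][0]) if infiltrated else None
    side = _side_of(regions[mig_mask][0]) if migrated else None
    reverse = False
    if infiltrated:
        after = frames > first_infiltration
        reverse = bool(
            np.isin(regions[after], ["channel_left", "channel_right"]).any()
        )
    return {
        "migrated": migrated,
        "infiltrated": infiltrated,
        "first_entry_frame": first_entry,
        "first_infiltration_frame": first_infiltration,
        "side": side,
        "reverse_crossing": reverse,
    }


def count_by_window(
    tracks: pd.DataFrame,
    windows: WindowSpec,
    frame_interval: float,
) -> pd.DataFrame:
    """Per-side, per-window counts of migrating and infiltrated cells.

    A cell is counted in the window containing its qualifying event frame
    (first channel entry for 'migrating', first tumor entry for
    'infiltrated'), once per category. ``frame_interval`` is in minutes.
    """
    rows = {
        (side, windows.label(w)): {"migrating": 0, "infiltrated": 0}
        for side in ("left", "right")
        for w in range(len(windows.windows))
    }
    if "region" not in tracks.columns:
        raise ValueError("tracks must be region-annotated (see annotate_regions)")
    for _, track in tracks.groupby("track_id"):
        status = classify_migration(track)
        if not status["migrated"]:
            continue
        side = status["side"]
        w = windows.window_of(status["first_entry_frame"] * frame_interval / 60.0)
        if w is not None and side is not None:
            rows[(side, windows.label(w))]["migrating"] += 1
        if status["infiltrated"]:
            wi = windows.window_of(
                status["first_infiltration_frame"] * frame_interval / 60.0
            )
            if wi is not None and side is not None:
                rows[(side, windows.label(wi))]["infiltrated"] += 1
    out = pd.DataFrame(
        [
            {"side": side, "window": win, **counts}
            for (side, win), counts in rows.items()
        ]
    )
    return out.sort_values(["side", "window"]).reset_index(drop=True)


def fold_increase(count_condition: float, count_control: float) -> float:
    """Ratio of infiltrated counts, condition over control; NaN if control = 0."""
    if count_control == 0:
        logger.warning("fold increase undefined: control count is zero")
        return float("nan")
    return count_condition / count_control


# ---------------------------------------------------------------------------
# per-window metric table


def _run_speed(track: pd.DataFrame, mask: np.ndarray, frame_interval: float) -> float:
    """Speed over the masked points of a track (path over masked polyline)."""
    sub = track[mask]
    if len(sub) < 2:
        return float("nan")
    xy = sub[["x_um", "y_um"]].to_numpy(float)
    duration = (sub["frame"].iloc[-1] - sub["frame"].iloc[0]) * frame_interval
    return speed(xy, duration)


def window_metrics(
    tracks: pd.DataFrame,
    windows: WindowSpec,
    frame_interval: float,
    classes: tuple[str, ...] = ("dc",),
    layout: DeviceLayout | None = None,
) -> pd.DataFrame:
    """Per-track, per-window motion metrics table.

    Each track contributes at most one row per window, computed on its
    sub-segment inside the window, provided the sub-segment has at least
    ``windows.min_frames_in_window`` points. Pre-channel speed is computed
    on immune-chamber points before the track's first channel entry;
    post-channel speed on tumor-chamber points from the first infiltration
    on (channel frames contribute to neither). Both displacement modes are
    emitted. Requires region-annotated tracks.

    The ``side`` of a row is the side the cell migrated to; cells that never
    left the immune chamber are sided by which half of the device their
    window segment occupies (when ``layout`` is given), matching how
    condition-resolved speeds are reported for chamber-resident cells in
    two-sided competition assays.
    """
    if "region" not in tracks.columns:
        raise ValueError("tracks must be region-annotated (see annotate_regions)")
    mid_x = None
    if layout is not None:
        mid_x = layout.immune_chamber.center[0]
    rows = []
    for tid, track in tracks.groupby("track_id"):
        if track["class"].iloc[0] not in classes:
            continue
        track = track.sort_values("frame").reset_index(drop=True)
        status = classify_migration(track)
        frames = track["frame"].to_numpy()
        hours = frames * frame_interval / 60.0
        for w, (ws, we) in enumerate(windows.windows):
            in_w = (hours >= ws) & (hours < we)
            if in_w.sum() < windows.min_frames_in_window:
                continue
            seg = track[in_w]
            xy = seg[["x_um", "y_um"]].to_numpy(float)
            duration = (seg["frame"].iloc[-1] - seg["frame"].iloc[0]) * frame_interval
            side = status["side"]
            if side is None and mid_x is not None:
                side = "left" if xy[:, 0].mean() < mid_x else "right"
            pre_mask = in_w & (track["region"] == "immune").to_numpy()
            if status["first_entry_frame"] is not None:
                pre_mask &= frames < status["first_entry_frame"]
            post_mask = in_w & np.isin(track["region"].to_numpy(), list(TUMOR_REGIONS))
            if status["first_infiltration_frame"] is not None:
                post_mask &= frames >= status["first_infiltration_frame"]
            else:
                post_mask &= False
            rows.append(
                {
                    "track_id": tid,
                    "window": windows.label(w),
                    "side": side,
                    "n_points": int(in_w.sum()),
                    "path_length_um": path_length(xy),
                    "displacement_euclidean_um": displacement(xy, "euclidean"),
                    "displacement_horizontal_um": displacement(xy, "horizontal"),
                    "dp": directional_persistence(xy),
                    "speed_um_min": speed(xy, duration),
                    "pre_channel_speed_um_min": _run_speed(track, pre_mask, frame_interval),
                    "post_channel_speed_um_min": _run_speed(track, post_mask, frame_interval),
                    "migrated": status["migrated"],
                    "infiltrated": status["infiltrated"],
                }
            )
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)
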