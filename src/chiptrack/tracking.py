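"""Trajectory construction: frame-to-frame linking with gating and gap closing.

Detections of one class are linked between consecutive frames by a
minimum-total-cost one-to-one assignment (Jonker-Volgenant solve on an
augmented cost matrix). The cost of a candidate link is its squared
displacement; candidates farther than the gate are forbidden, and every
detection carries an alternative "start new track"/"terminate" option with
cost gate², so the solver trades off linking against birth/death exactly as
in the standard linear-assignment tracking formulation. A second pass
merges a track end with a compatible later track start (gap closing),
filling skipped frames by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "LinkParams",
    "link_frames",
    "close_gaps",
    "track_stack",
    "assignment_cost",
    "TRACK_COLUMNS",
]

TRACK_COLUMNS = ["track_id", "class", "frame", "x_um", "y_um", "det_id", "interpolated"]

_FORBIDDEN = 1e12


@dataclass(frozen=True)
class LinkParams:
    """Linking controls.

    ``gate_distance`` is the maximum displacement allowed per frame interval
    (µm); the default 48 µm corresponds to 3x an expected step of a
    ~8 µm/min cell observed every 2 min. ``gap_frames`` is how many missing
    frames gap closing may bridge; ``min_track_length`` drops short tracks.
    """

    gate_distance: float = 48.0
    gap_frames: int = 2
    min_track_length: int = 5

    def __post_init__(self) -> None:
        if self.gate_distance <= 0:
            raise ValueError("gate_distance must be > 0")
        if self.gap_frames < 0:
            raise ValueError("gap_frames must be >= 0")


def assignment_cost(
    prev_xy: np.ndarray, next_xy: np.ndarray, gate: float
) -> tuple[list[tuple[int, int]], float]:
    """Optimal gated one-to-one assignment between two point sets.

    Minimizes sum of squared displacements of linked pairs plus gate² per
    unlinked point (the birth/death alternative). Returns the chosen links
    as (prev_index, next_index) pairs, sorted, and the total cost.
    """
    n, m = len(prev_xy), len(next_xy)
    if n == 0 or m == 0:
        return [], gate**2 * (n + m)
    d2 = ((prev_xy[:, None, :] - next_xy[None, :, :]) ** 2).sum(axis=2)
    cost = np.where(d2 <= gate**2, d2, _FORBIDDEN)
    aug = np.full((n + m, n + m), _FORBIDDEN)
    aug[:n, :m] = cost
    aug[:n, m:] = np.where(np.eye(n, dtype=bool), gate**2, _FORBIDDEN)  # deaths
    aug[n:, :m] = np.where(np.eye(m, dtype=bool), gate**2, _FORBIDDEN)  # births
    aug[n:, m:] = 0.0  # dummy-dummy
    rows, cols = linear_sum_assignment(aug)
    links = []
    total = 0.0
    for r, c in zip(rows, cols):
        total += aug[r, c]
        if r < n and c < m:
            links.append((int(r), int(c)))
    return sorted(links), float(total)


def link_frames(detections: pd.DataFrame, params: LinkParams) -> pd.DataFrame:
    """Link detections of one class across consecutive frames into raw tracks.

    ``detections`` must carry frame, x_um, y_um, det_id for a single class.
    Returns a track table (no interpolation yet). Ties in the underlying
    assignment are broken deterministically by (frame, det_id) ordering of
    the inputs.
    """
    if len(detections) == 0:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    det = detections.sort_values(["frame", "det_id"]).reset_index(drop=True)
    frames = sorted(det["frame"].unique())
    by_frame = {f: det[det["frame"] == f] for f in frames}

    next_track = 0
    track_of: dict[int, int] = {}  # det_id -> track_id
    for f in frames:
        for did in by_frame[f]["det_id"]:
            track_of.setdefault(int(did), -1)

    # seed tracks for the first frame
    for did in by_frame[frames[0]]["det_id"]:
        track_of[int(did)] = next_track
        next_track += 1

    for fa, fb in zip(frames[:-1], frames[1:]):
        a = by_frame[fa]
        b = by_frame[fb]
        if fb - fa == 1:
            links, _ = assignment_cost(
                a[["x_um", "y_um"]].to_numpy(float),
                b[["x_um", "y_um"]].to_numpy(float),
                params.gate_distance,
            )
        else:
            links = []  # non-adjacent frames: everything terminates/starts
        linked_b = set()
        for ia, ib in links:
            did_a = int(a["det_id"].iloc[ia])
            did_b = int(b["det_id"].iloc[ib])
            track_of[did_b] = track_of[did_a]
            linked_b.add(did_b)
        for did in b["det_id"]:
            did = int(did)
            if did not in linked_b:
                track_of[did] = next_track
                next_track += 1

    out = det.copy()
    out["track_id"] = [track_of[int(d)] for d in out["det_id"]]
    out["interpolated"] = False
    if "class" not in out.columns:
        out["class"] = "dc"
    return out[TRACK_COLUMNS].sort_values(["track_id", "frame"]).reset_index(drop=True)


def close_gaps(tracks: pd.DataFrame, params: LinkParams) -> pd.DataFrame:
    """Merge track ends with compatible later track starts.

    A candidate pair is a track end and a track start of the same class with
    frame gap g in [2, gap_frames+1] and distance <= gate_distance * g.
    Candidates are merged globally greedily by ascending squared distance;
    skipped frames are filled by linear interpolation and flagged.
    """
    if len(tracks) == 0 or params.gap_frames == 0:
        return tracks.copy()
    tracks = tracks.sort_values(["track_id", "frame"]).reset_index(drop=True)
    ends = tracks.groupby("track_id").tail(1).set_index("track_id")
    starts = tracks.groupby("track_id").head(1).set_index("track_id")

    e_ids = ends.index.to_numpy()
    s_ids = starts.index.to_numpy()
    g = starts["frame"].to_numpy()[None, :] - ends["frame"].to_numpy()[:, None]
    d2 = (starts["x_um"].to_numpy()[None, :] - ends["x_um"].to_numpy()[:, None]) ** 2 + (
        starts["y_um"].to_numpy()[None, :] - ends["y_um"].to_numpy()[:, None]
    ) ** 2
    same_class = (
        ends["class"].to_numpy()[:, None] == starts["class"].to_numpy()[None, :]
    )
    feasible = (
        same_class
        & (g >= 2)
        & (g <= params.gap_frames + 1)
        & (d2 <= (params.gate_distance * g.astype(float)) ** 2)
        & (e_ids[:, None] != s_ids[None, :])
    )
    ei, si = np.nonzero(feasible)
    candidates = sorted(
        (float(d2[a, b]), int(e_ids[a]), int(s_ids[b])) for a, b in zip(ei, si)
    )

    merged_into: dict[int, int] = {}
    used_ends: set[int] = set()
    used_starts: set[int] = set()
    fills = []
    for d2, tid_e, tid_s in candidates:
        root = tid_e
        while root in merged_into:
            root = merged_into[root]
        if tid_e in used_ends or tid_s in used_starts or root == tid_s:
            continue
        used_ends.add(tid_e)
        used_starts.add(tid_s)
        merged_into[tid_s] = tid_e
        end = ends.loc[tid_e]
        start = starts.loc[tid_s]
        g = int(start["frame"] - end["frame"])
        for k in range(1, g):
            w = k / g
            fills.append(
                {
                    "track_id": tid_s,  # remapped below
                    "class": end["class"],
                    "frame": int(end["frame"]) + k,
                    "x_um": (1 - w) * end["x_um"] + w * start["x_um"],
                    "y_um": (1 - w) * end["y_um"] + w * start["y_um"],
                    "det_id": -1,
                    "interpolated": True,
                }
            )

    def root_of(tid: int) -> int:
        while tid in merged_into:
            tid = merged_into[tid]
        return tid

    out = tracks.copy()
    out["track_id"] = out["track_id"].map(root_of)
    if fills:
        fill_df = pd.DataFrame(fills)
        fill_df["track_id"] = fill_df["track_id"].map(root_of)
        out = pd.concat([out, fill_df], ignore_index=True)
    return out.sort_values(["track_id", "frame"]).reset_index(drop=True)


def track_stack(detections: pd.DataFrame, params: LinkParams | None = None) -> pd.DataFrame:
    """Full linking pipeline: per-class linking, gap closing, length filter.

    Track ids are renumbered densely in (class, first frame, det_id) order
    so output is deterministic.
    """
    params = params or LinkParams()
    if len(detections) == 0:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    parts = []
    offset = 0
    for cls in sorted(detections["class"].unique()):
        sub = detections[detections["class"] == cls]
        linked = link_frames(sub, params)
        linked = close_gaps(linked, params)
        lengths = linked.groupby("track_id")["frame"].count()
        keep = lengths[lengths >= params.min_track_length].index
        linked = linked[linked["track_id"].isin(keep)]
        if len(linked):
            remap = {
                tid: offset + i
                for i, tid in enumerate(
                    linked.groupby("track_id")["frame"].min().sort_values().index
                )
            }
            linked = linked.copy()
            linked["track_id"] = linked["track_id"].map(remap)
            offset += len(remap)
            parts.append(linked)
    if not parts:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    return (
        pd.concat(parts, ignore_index=True)
        .sort_values(["track_id", "frame"])
        .reset_index(drop=True)
    )


def save_tracks(tracks: pd.DataFrame, path) -> None:
    tracks.to_csv(path, index=False)


def load_tracks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("track_id", "class", "frame", "x_um", "y_um") if c not in df.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    if "det_id" not in df.columns:
        df["det_id"] = -1
    if "interpolated" not in df.columns:
        df["interpolated"] = False
    return df[TRACK_COLUMNS]
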