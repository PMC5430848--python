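"""Run orchestration: configuration, end-to-end execution, file outputs.

A run is described by a :class:`RunConfig` (plain-YAML serializable, every
default materialized on load) and executes detection → tracking → motility
→ interaction → group summaries, writing each stage's table as CSV plus a
manifest that records the fully-resolved configuration, a config hash and
package versions, so runs are self-describing and byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detection import FrameStack, SegmentationParams, detect_stack
from .geometry import DeviceLayout, make_default_layout
from .interaction import detect_interactions, mean_interaction_time
from .motility import WindowSpec, annotate_regions, count_by_window, window_metrics
from .simulate import NoiseModel, SimulationConfig, export_truth, render_stack, simulate_tracks
from .stats import compare_groups, summarize_groups
from .tracking import LinkParams, track_stack

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "simulate_command"]

COMPARED_METRICS = (
    "dp",
    "speed_um_min",
    "pre_channel_speed_um_min",
    "post_channel_speed_um_min",
    "displacement_euclidean_um",
    "displacement_horizontal_um",
)


@dataclass
class RunConfig:
    """Fully-resolved configuration of one analysis run.

    ``stack_paths`` maps channel role to a multi-page TIFF; when empty, the
    stack is produced by the built-in simulator from the ``simulation``
    block (rendered every ``render_every`` truth frames at the stack's
    effective frame interval). ``condition_labels`` names the biological
    condition on each side of the device.
    """

    output_dir: str = "chiptrack_run"
    stack_paths: dict = field(default_factory=dict)
    layout_path: str | None = None
    pixel_size: float = 4.0  # µm/px
    frame_interval: float = 2.0  # min (acquisition clock of the stack)
    n_channels_per_side: int = 10
    mask_mode: str = "layout"
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    linking: LinkParams = field(default_factory=LinkParams)
    windows: WindowSpec = field(default_factory=WindowSpec)
    interaction_radius: float = 20.0  # µm, mandatory logged choice
    interaction_gap_tolerance: int = 1
    condition_labels: dict = field(default_factory=lambda: {"left": "NT", "right": "RI"})
    simulation: SimulationConfig | None = None
    render_every: int = 1
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(background=20.0, shot_scale=1.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("config field 'pixel_size' must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("config field 'frame_interval' must be > 0")
        if self.interaction_radius <= 0:
            raise ValueError("config field 'interaction_radius' must be > 0")

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["windows"] = {
            "windows": [list(w) for w in self.windows.windows],
            "min_frames_in_window": self.windows.min_frames_in_window,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "pixel_size" in d and d["pixel_size"] is None:
            raise ValueError("config field 'pixel_size' must not be null")
        if isinstance(d.get("segmentation"), dict):
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        if isinstance(d.get("linking"), dict):
            d["linking"] = LinkParams(**d["linking"])
        if isinstance(d.get("windows"), dict):
            w = d["windows"]
            d["windows"] = WindowSpec(
                windows=tuple(tuple(x) for x in w.get("windows", WindowSpec().windows)),
                min_frames_in_window=w.get("min_frames_in_window", 5),
            )
        if isinstance(d.get("simulation"), dict):
            d["simulation"] = SimulationConfig(**d["simulation"])
        if isinstance(d.get("noise"), dict):
            d["noise"] = NoiseModel(**d["noise"])
        return cls(**d)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _resolve_layout(config: RunConfig) -> DeviceLayout:
    if config.layout_path:
        return DeviceLayout.load(config.layout_path)
    return make_default_layout(
        config.pixel_size, n_channels_per_side=config.n_channels_per_side
    )


def _resolve_stack(config: RunConfig, layout: DeviceLayout, out: Path):
    if config.stack_paths:
        stack = FrameStack.load(
            config.stack_paths, config.frame_interval, config.pixel_size
        )
        if stack.pixel_size != layout.pixel_size:
            raise ValueError(
                f"calibration mismatch: stack pixel_size {stack.pixel_size} vs "
                f"layout {layout.pixel_size}"
            )
        return stack, None
    if config.simulation is None:
        raise ValueError("config must provide either 'stack_paths' or a 'simulation' block")
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    tracks = simulate_tracks(sim, layout)
    every = max(1, config.render_every)
    frame_indices = np.arange(0, sim.n_frames, every)
    stack = render_stack(
        tracks,
        layout,
        config.noise,
        frame_interval=sim.frame_interval * every,
        frame_indices=frame_indices,
        seed=config.seed,
    )
    export_truth(tracks, out / "ground_truth.csv")
    return stack, tracks


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the result bundle.

    Returns a dict with the in-memory tables (detections, tracks, metrics,
    counts, events, interaction_times, summaries) and the manifest.
    Deterministic given config + seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = _resolve_layout(config)
    layout.save(out / "layout.yaml")
    stack, _truth = _resolve_stack(config, layout, out)

    detections = detect_stack(stack, layout, config.segmentation, config.mask_mode)
    tracks = track_stack(detections, config.linking)
    tracks = annotate_regions(tracks, layout)
    frame_interval = stack.frame_interval

    dc_tracks = tracks[tracks["class"] == "dc"]
    cancer_tracks = tracks[tracks["class"] == "cancer"]
    metrics = window_metrics(tracks, config.windows, frame_interval, layout=layout)
    counts = count_by_window(dc_tracks, config.windows, frame_interval)
    events = detect_interactions(
        dc_tracks,
        cancer_tracks,
        config.interaction_radius,
        frame_interval,
        config.interaction_gap_tolerance,
    )
    itimes = mean_interaction_time(events, config.windows, frame_interval)

    summaries = []
    for metric in COMPARED_METRICS:
        if metric not in metrics.columns or metrics.empty:
            continue
        summ = summarize_groups(
            metrics, metric, condition_labels=config.condition_labels
        )
        for window in metrics["window"].unique():
            a = metrics[(metrics["side"] == "left") & (metrics["window"] == window)][
                metric
            ].dropna()
            b = metrics[(metrics["side"] == "right") & (metrics["window"] == window)][
                metric
            ].dropna()
            test = compare_groups(a, b)
            summ.loc[summ["window"] == window, "t_left_vs_right"] = test["t"]
            summ.loc[summ["window"] == window, "p_left_vs_right"] = test["p"]
        summaries.append(summ)
    summaries = (
        pd.concat(summaries, ignore_index=True)
        if summaries
        else pd.DataFrame(columns=["metric", "condition", "side", "window", "n", "mean", "sd", "sem"])
    )

    detections.to_csv(out / "detections.csv", index=False)
    tracks.to_csv(out / "tracks.csv", index=False)
    metrics.to_csv(out / "metrics.csv", index=False)
    counts.to_csv(out / "counts.csv", index=False)
    events.to_csv(out / "interactions.csv", index=False)
    itimes.to_csv(out / "interaction_times.csv", index=False)
    summaries.to_csv(out / "summaries.csv", index=False)

    manifest = {
        "chiptrack_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_frames": int(stack.n_frames),
        "frame_interval_min": float(frame_interval),
        "n_detections": int(len(detections)),
        "n_tracks": int(tracks["track_id"].nunique()) if len(tracks) else 0,
        "n_events": int(len(events)),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return {
        "layout": layout,
        "stack": stack,
        "detections": detections,
        "tracks": tracks,
        "metrics": metrics,
        "counts": counts,
        "events": events,
        "interaction_times": itimes,
        "summaries": summaries,
        "manifest": manifest,
    }


def simulate_command(config: RunConfig) -> dict:
    """Generate a synthetic stack + ground-truth table without analysing it."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = _resolve_layout(config)
    if config.simulation is None:
        raise ValueError("config must provide a 'simulation' block")
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    tracks = simulate_tracks(sim, layout)
    every = max(1, config.render_every)
    frame_indices = np.arange(0, sim.n_frames, every)
    stack = render_stack(
        tracks,
        layout,
        config.noise,
        frame_interval=sim.frame_interval * every,
        frame_indices=frame_indices,
        seed=config.seed,
    )
    paths = stack.save(str(out / "stack"))
    export_truth(tracks, out / "ground_truth.csv")
    layout.save(out / "layout.yaml")
    return {"stack_paths": paths, "truth_path": str(out / "ground_truth.csv"), "stack": stack}
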