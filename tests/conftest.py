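"""Shared fixtures: layouts, scripted tracks, and the standard biased run."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from chiptrack import (
    LinkParams,
    RunConfig,
    SimulationConfig,
    WindowSpec,
    make_default_layout,
    run_pipeline,
)
from chiptrack.simulate import GroundTruthTrack

logging.getLogger("chiptrack").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def layout2():
    """Default device layout at 2 µm/px."""
    return make_default_layout(2.0)


@pytest.fixture(scope="session")
def layout4():
    """Default device layout at 4 µm/px (coarse, fast rendering)."""
    return make_default_layout(4.0)


def make_static_track(agent_id, cls, x_um, y_um, n_frames, born=0):
    pos = np.tile([x_um, y_um], (n_frames, 1)).astype(float)
    return GroundTruthTrack(agent_id=agent_id, agent_class=cls, born=born, positions=pos)


def make_moving_track(agent_id, cls, start, velocity_um_per_frame, n_frames, born=0):
    t = np.arange(n_frames)[:, None]
    pos = np.asarray(start, float) + t * np.asarray(velocity_um_per_frame, float)
    return GroundTruthTrack(agent_id=agent_id, agent_class=cls, born=born, positions=pos)


def grid_tracks(layout, n, spacing_um, cls="dc", n_frames=1, region="immune"):
    """n static agents on a grid inside one compartment, spacing apart."""
    rect = {
        "immune": layout.immune_chamber,
        "tumor_left": layout.tumor_chambers["left"],
        "tumor_right": layout.tumor_chambers["right"],
    }[region]
    margin = 15.0
    xs = np.arange(rect.x0 + margin, rect.x1 - margin, spacing_um)
    ys = np.arange(rect.y0 + margin, rect.y1 - margin, spacing_um)
    coords = [(x, y) for y in ys for x in xs][:n]
    if len(coords) < n:
        raise ValueError("compartment too small for requested grid")
    return [
        make_static_track(i, cls, x, y, n_frames) for i, (x, y) in enumerate(coords)
    ]


STANDARD_FIXTURE_SEED = 42


def standard_biased_config(output_dir, seed=STANDARD_FIXTURE_SEED):
    """The standard biased-vs-unbiased 72 h co-culture fixture.

    Half the immune cells sense a strong chemotactic cue (bias 0.8) toward
    the right tumor chamber; the rest walk unbiased. Cells activate
    uniformly over the movie, as in the sustained-recruitment kinetics the
    assay shows. Truth at 2-min frames; rendered every 3rd frame (6-min
    stack) at 4 µm/px to keep the rendered movie at desk scale.
    """
    sim = SimulationConfig(
        n_dcs=100,
        n_cancer_per_chamber=10,
        n_frames=2160,
        frame_interval=2.0,
        speed_mean=5.0,
        speed_sd=1.5,
        persistence=2.0,
        bias_strength=0.8,
        bias_side="right",
        biased_fraction=0.5,
        birth_stagger_frames=2160,
        seed=seed,
    )
    return RunConfig(
        output_dir=str(output_dir),
        pixel_size=4.0,
        simulation=sim,
        render_every=3,
        seed=seed,
        linking=LinkParams(gate_distance=90.0, gap_frames=2, min_track_length=5),
        windows=WindowSpec(min_frames_in_window=5),
    )


@pytest.fixture(scope="session")
def standard_run(tmp_path_factory):
    """Pipeline results on the standard biased fixture (computed once)."""
    out = tmp_path_factory.mktemp("standard_run")
    return run_pipeline(standard_biased_config(out))
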