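"""Synthetic ground truth for the co-culture tracking pipeline.

Generates known-truth trajectories inside a :class:`~chiptrack.geometry.DeviceLayout`
and renders them to noisy fluorescence-like movies, so that every analysis
stage (segmentation, linking, motility metrics) can be validated against an
exact answer.

Motile immune agents (dendritic-cell-like spots) follow a confined biased
persistent random walk: the heading evolves by wrapped-normal turns around
the previous heading (concentration ``persistence``), blended with a drift
vector toward a target tumor chamber weighted by ``bias_strength``; step
lengths are positive-truncated normal with mean ``speed_mean * dt``. Walls
of the allowed compartments (immune chamber, connecting channels, tumor
chambers) reflect the motion; agents can only reach a tumor chamber by
traversing a connecting channel, as in the physical chip. Cancer agents are
near-static spots jittering inside the tumor chambers, mimicking
collagen-embedded cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .geometry import LABEL_CODE, DeviceLayout, classify_points

__all__ = [
    "SimulationConfig",
    "NoiseModel",
    "simulate_tracks",
    "render_stack",
    "render_frame",
    "export_truth",
    "load_truth",
]

ALLOWED_CODES = frozenset(
    LABEL_CODE[name]
    for name in ("immune", "channel_left", "channel_right", "tumor_left", "tumor_right")
)

TRUTH_COLUMNS = ["agent_id", "class", "frame", "x_um", "y_um"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic co-culture run.

    Defaults mirror the assay: frames every 2 min, cells of ~10-18 µm
    diameter, immune agents at a few µm/min. ``bias_strength`` in [0, 1]
    scales the chemotactic drift toward ``bias_side``'s tumor chamber
    (0 = unbiased persistent random walk, 1 = pure drift). ``persistence``
    is the turning-angle concentration (0 = fresh uniform heading each
    step; large = nearly straight).
    """

    n_dcs: int = 50
    n_cancer_per_chamber: int = 15
    frame_interval: float = 2.0  # min
    n_frames: int = 180
    speed_mean: float = 5.0  # µm/min
    speed_sd: float = 1.5  # µm/min
    persistence: float = 2.0
    bias_strength: float = 0.0
    bias_side: str = "right"
    biased_fraction: float = 1.0  # fraction of immune agents that sense the bias
    birth_stagger_frames: int = 0  # agents activate at a uniform frame in [0, this]
    patrol_capture_radius: float = 15.0  # µm; reaching the target resamples it
    patrol_dwell_frames: float = 7.0  # mean pause (frames) at a reached target
    cancer_jitter_sd: float = 0.3  # µm/frame
    dc_radius: float = 7.0  # µm
    cancer_radius: float = 9.0  # µm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed_mean <= 0:
            raise ValueError("speed_mean must be > 0")
        if not 0.0 <= self.bias_strength <= 1.0:
            raise ValueError("bias_strength must be in [0, 1]")
        if not 0.0 <= self.biased_fraction <= 1.0:
            raise ValueError("biased_fraction must be in [0, 1]")
        if self.birth_stagger_frames < 0:
            raise ValueError("birth_stagger_frames must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.persistence < 0:
            raise ValueError("persistence must be >= 0")
        if self.bias_side not in ("left", "right"):
            raise ValueError("bias_side must be 'left' or 'right'")


@dataclass(frozen=True)
class NoiseModel:
    """Microscope noise: constant offset, linear x-gradient, blur, shot noise.

    ``shot_scale`` is the photon-count scale of the Poisson shot-noise model
    (0 disables it); ``blur_sigma_px`` is extra optical blur applied on top
    of each spot's intrinsic Gaussian profile.
    """

    background: float = 0.0
    gradient: float = 0.0  # intensity units per full image width
    blur_sigma_px: float = 0.0
    shot_scale: float = 0.0


@dataclass
class GroundTruthTrack:
    """True per-frame positions of one agent."""

    agent_id: int
    agent_class: str  # "dc" | "cancer"
    born: int
    positions: np.ndarray = field(repr=False)  # (n_frames_alive, 2) µm

    @property
    def died(self) -> int:
        return self.born + len(self.positions) - 1

    def frames(self) -> np.ndarray:
        return np.arange(self.born, self.born + len(self.positions))


def _sample_positive_normal(rng, mean: float, sd: float, size: int) -> np.ndarray:
    """Positive-truncated normal via rejection (fast for mean >> 0)."""
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def _allowed(layout: DeviceLayout, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    h_um, w_um = layout.extent_um
    inside = (x >= 0) & (x < w_um) & (y >= 0) & (y < h_um)
    codes = np.full(x.shape, -1, dtype=np.int8)
    if inside.any():
        codes[inside] = classify_points(layout, x[inside], y[inside])
    out = np.zeros(x.shape, dtype=bool)
    for code in ALLOWED_CODES:
        out |= codes == code
    return out


def _segment_allowed(
    layout: DeviceLayout,
    x: np.ndarray,
    y: np.ndarray,
    dx: np.ndarray,
    dy: np.ndarray,
    check_um: float = 3.0,
) -> np.ndarray:
    """True where the straight segment (x,y)->(x+dx,y+dy) stays in allowed
    regions, checked at points spaced <= ``check_um`` apart (no tunnelling
    through compartment walls)."""
    if len(x) == 0:
        return np.zeros(0, dtype=bool)
    max_len = float(np.hypot(dx, dy).max())
    n_checks = max(1, int(math.ceil(max_len / check_um)))
    ok = np.ones(len(x), dtype=bool)
    for i in range(1, n_checks + 1):
        f = i / n_checks
        ok &= _allowed(layout, x + f * dx, y + f * dy)
        if not ok.any():
            break
    return ok


def _move_reflect(
    layout: DeviceLayout,
    x: np.ndarray,
    y: np.ndarray,
    dx: np.ndarray,
    dy: np.ndarray,
    substep_um: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance agents by (dx, dy), reflecting at compartment walls.

    The step is split into substeps of at most ``substep_um``; at each
    substep a move into a forbidden region is retried with the x and/or y
    velocity component mirrored, otherwise the agent stalls for that
    substep. This confines agents to the immune chamber, channels and tumor
    chambers while letting them slide along walls and funnel into channel
    entries.
    """
    if len(x) == 0:
        return x, y
    step_len = np.hypot(dx, dy)
    n_sub = max(1, int(math.ceil(step_len.max() / substep_um)))
    sx = dx / n_sub
    sy = dy / n_sub
    for _ in range(n_sub):
        done = np.zeros(len(x), dtype=bool)
        for mx, my in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
            cand_x = mx * sx
            cand_y = my * sy
            nx = x + cand_x
            ny = y + cand_y
            ok = ~done & _allowed(layout, nx, ny)
            x = np.where(ok, nx, x)
            y = np.where(ok, ny, y)
            # keep the (possibly mirrored) velocity for the remaining substeps
            sx = np.where(ok, cand_x, sx)
            sy = np.where(ok, cand_y, sy)
            done |= ok
            if done.all():
                break
    return x, y


def simulate_tracks(
    config: SimulationConfig, layout: DeviceLayout
) -> list[GroundTruthTrack]:
    """Simulate ground-truth trajectories for all agents.

    Immune agents start uniformly in the immune chamber; cancer agents are
    split evenly between the two tumor chambers (alternating sides) and
    jitter in place. Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    tracks: list[GroundTruthTrack] = []
    if config.n_frames <= 0:
        return tracks
    dt = config.frame_interval

    # cancer rest positions are sampled first so they can anchor the patrol
    # targets of chemotactically biased immune agents
    cancer_init: dict[str, np.ndarray] = {}
    for side in ("left", "right"):
        m = config.n_cancer_per_chamber
        if m <= 0:
            continue
        cham = layout.tumor_chambers[side]
        pad = config.cancer_radius
        cancer_init[side] = np.column_stack(
            [
                rng.uniform(cham.x0 + pad, cham.x1 - pad, m),
                rng.uniform(cham.y0 + pad, cham.y1 - pad, m),
            ]
        )

    # --- immune agents -----------------------------------------------------
    n = config.n_dcs
    if n > 0:
        imm = layout.immune_chamber
        cham = layout.tumor_chambers[config.bias_side]
        anchors = cancer_init.get(config.bias_side)

        def sample_targets(k: int) -> tuple[np.ndarray, np.ndarray]:
            """Patrol targets: near a random cancer cell, else uniform."""
            if anchors is not None and len(anchors):
                pick = anchors[rng.integers(0, len(anchors), k)]
                tx = np.clip(pick[:, 0] + rng.normal(0, 5.0, k), cham.x0 + 2, cham.x1 - 2)
                ty = np.clip(pick[:, 1] + rng.normal(0, 5.0, k), cham.y0 + 2, cham.y1 - 2)
                return tx, ty
            return (
                rng.uniform(cham.x0 + 5.0, cham.x1 - 5.0, k),
                rng.uniform(cham.y0 + 5.0, cham.y1 - 5.0, k),
            )

        x = rng.uniform(imm.x0 + 1.0, imm.x1 - 1.0, n)
        y = rng.uniform(imm.y0 + 1.0, imm.y1 - 1.0, n)
        theta = rng.uniform(-np.pi, np.pi, n)
        # the first biased_fraction of agents sense the chemotactic cue; each
        # homes to its own target (a cancer cell of the biased chamber) and
        # patrols between targets with a pause on arrival, rather than piling
        # up at a single attractor point
        n_biased = int(round(config.biased_fraction * n))
        b_arr = np.where(np.arange(n) < n_biased, config.bias_strength, 0.0)
        tgt_x, tgt_y = sample_targets(n)
        pause_left = np.zeros(n, dtype=int)
        needs_retarget = np.zeros(n, dtype=bool)
        born = (
            rng.integers(0, config.birth_stagger_frames + 1, n)
            if config.birth_stagger_frames > 0
            else np.zeros(n, dtype=int)
        )
        pos = np.empty((config.n_frames, n, 2))
        pos[0, :, 0] = x
        pos[0, :, 1] = y
        sigma_turn = (
            None if config.persistence == 0 else 1.0 / math.sqrt(config.persistence)
        )
        any_bias = config.bias_strength > 0 and n_biased > 0
        for t in range(1, config.n_frames):
            retarget = needs_retarget & (pause_left == 0)
            if retarget.any():
                k = int(retarget.sum())
                tgt_x[retarget], tgt_y[retarget] = sample_targets(k)
                needs_retarget[retarget] = False
            step = _sample_positive_normal(
                rng, config.speed_mean * dt, config.speed_sd * dt, n
            )
            step[born >= t] = 0.0  # not yet activated
            step[pause_left > 0] = 0.0  # dwelling at a reached target
            # rejection-sample headings so the full step stays inside the
            # culture compartments (cells turn at walls rather than walk into
            # them); this keeps the realized step length equal to the sampled
            # one. Agents still blocked after the attempts (e.g. pure drift
            # pressed against a wall) fall back to mirrored reflection.
            accepted = step == 0.0
            for _attempt in range(12):
                idx = np.flatnonzero(~accepted)
                if len(idx) == 0:
                    break
                if sigma_turn is None:
                    th = rng.uniform(-np.pi, np.pi, len(idx))
                else:
                    th = theta[idx] + rng.normal(0.0, sigma_turn, len(idx))
                dirx = np.cos(th)
                diry = np.sin(th)
                if any_bias:
                    b = b_arr[idx]
                    bx = tgt_x[idx] - x[idx]
                    by = tgt_y[idx] - y[idx]
                    norm = np.hypot(bx, by)
                    norm[norm == 0] = 1.0
                    dirx = (1 - b) * dirx + b * bx / norm
                    diry = (1 - b) * diry + b * by / norm
                    norm = np.hypot(dirx, diry)
                    small = norm < 1e-9
                    dirx = np.where(small, np.cos(th), dirx / np.maximum(norm, 1e-9))
                    diry = np.where(small, np.sin(th), diry / np.maximum(norm, 1e-9))
                dx = dirx * step[idx]
                dy = diry * step[idx]
                ok = _segment_allowed(layout, x[idx], y[idx], dx, dy)
                hit = idx[ok]
                x[hit] += dx[ok]
                y[hit] += dy[ok]
                theta[hit] = np.arctan2(dy[ok], dx[ok])
                accepted[hit] = True
            idx = np.flatnonzero(~accepted)
            if len(idx):
                nx, ny = _move_reflect(
                    layout, x[idx].copy(), y[idx].copy(),
                    np.cos(theta[idx]) * step[idx], np.sin(theta[idx]) * step[idx],
                )
                moved = np.hypot(nx - x[idx], ny - y[idx])
                realized = np.arctan2(ny - y[idx], nx - x[idx])
                theta[idx] = np.where(moved > 1e-6, realized, theta[idx])
                x[idx] = nx
                y[idx] = ny
            pause_left = np.maximum(pause_left - 1, 0)
            if any_bias:
                reached = np.hypot(tgt_x - x, tgt_y - y) <= config.patrol_capture_radius
                reached &= (b_arr > 0) & (pause_left == 0) & ~needs_retarget
                k = int(reached.sum())
                if k:
                    if config.patrol_dwell_frames > 0:
                        pause_left[reached] = rng.geometric(
                            1.0 / max(config.patrol_dwell_frames, 1.0), k
                        )
                    needs_retarget[reached] = True
            pos[t, :, 0] = x
            pos[t, :, 1] = y
        for i in range(n):
            tracks.append(
                GroundTruthTrack(
                    agent_id=i,
                    agent_class="dc",
                    born=int(born[i]),
                    positions=pos[born[i] :, i, :].copy(),
                )
            )

    # --- cancer agents -----------------------------------------------------
    next_id = config.n_dcs
    for side in ("left", "right"):
        if side not in cancer_init:
            continue
        m = config.n_cancer_per_chamber
        cham = layout.tumor_chambers[side]
        cx = cancer_init[side][:, 0]
        cy = cancer_init[side][:, 1]
        jit = rng.normal(0.0, config.cancer_jitter_sd, (config.n_frames, m, 2))
        pos = np.empty((config.n_frames, m, 2))
        pos[:, :, 0] = np.clip(cx + np.cumsum(jit[:, :, 0], axis=0), cham.x0 + 1, cham.x1 - 1)
        pos[:, :, 1] = np.clip(cy + np.cumsum(jit[:, :, 1], axis=0), cham.y0 + 1, cham.y1 - 1)
        for i in range(m):
            tracks.append(
                GroundTruthTrack(
                    agent_id=next_id + i,
                    agent_class="cancer",
                    born=0,
                    positions=pos[:, i, :].copy(),
                )
            )
        next_id += m
    return tracks


def render_frame(
    positions: np.ndarray,
    amplitudes: np.ndarray,
    sigmas_px: np.ndarray,
    shape: tuple[int, int],
    pixel_size: float,
) -> np.ndarray:
    """Draw Gaussian spots (µm positions) onto a (H, W) float image."""
    h, w = shape
    img = np.zeros((h, w), dtype=np.float64)
    for (x_um, y_um), amp, sig in zip(positions, amplitudes, sigmas_px):
        # pixel index i samples the physical position (i + 0.5) * pixel_size
        cx = x_um / pixel_size - 0.5
        cy = y_um / pixel_size - 0.5
        r = int(math.ceil(4 * sig))
        x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, w)
        y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1) - cx
        ys = np.arange(y0, y1) - cy
        g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sig**2))
        img[y0:y1, x0:x1] += amp * g
    return img


def render_stack(
    tracks: list[GroundTruthTrack],
    layout: DeviceLayout,
    noise: NoiseModel | None = None,
    *,
    frame_interval: float = 2.0,
    frame_indices: np.ndarray | None = None,
    dc_amplitude: float = 150.0,
    cancer_amplitude: float = 150.0,
    dc_sigma_um: float = 3.5,
    cancer_sigma_um: float = 4.5,
    seed: int = 0,
):
    """Render ground-truth tracks to a two-channel fluorescence movie.

    Each agent is a 2D Gaussian spot (sigma = half its radius by default) on
    the channel of its class. Returns a :class:`~chiptrack.detection.FrameStack`.
    ``frame_indices`` selects a subset of truth frames to render (temporal
    downsampling); ``frame_interval`` is the interval of the *rendered*
    stack in minutes.
    """
    from .detection import FrameStack  # local import to avoid cycle

    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    h, w = layout.image_extent
    ps = layout.pixel_size
    all_frames = sorted({f for tr in tracks for f in tr.frames()}) or [0]
    if frame_indices is None:
        frame_indices = np.asarray(all_frames if tracks else [0])
    frame_indices = np.asarray(frame_indices)

    eff_sigma = {
        "dc": math.hypot(dc_sigma_um / ps, noise.blur_sigma_px),
        "cancer": math.hypot(cancer_sigma_um / ps, noise.blur_sigma_px),
    }
    amp = {"dc": dc_amplitude, "cancer": cancer_amplitude}

    background = np.full((h, w), noise.background, dtype=np.float64)
    if noise.gradient:
        background += noise.gradient * (np.arange(w) / max(w - 1, 1))[None, :]

    channels: dict[str, np.ndarray] = {}
    for cls in ("dc", "cancer"):
        cls_tracks = [t for t in tracks if t.agent_class == cls]
        frames = np.empty((len(frame_indices), h, w), dtype=np.float32)
        for k, fi in enumerate(frame_indices):
            pos = []
            for tr in cls_tracks:
                if tr.born <= fi <= tr.died:
                    pos.append(tr.positions[fi - tr.born])
            pos = np.asarray(pos).reshape(-1, 2)
            img = render_frame(
                pos,
                np.full(len(pos), amp[cls]),
                np.full(len(pos), eff_sigma[cls]),
                (h, w),
                ps,
            )
            img += background
            if noise.shot_scale > 0:
                img = rng.poisson(np.clip(img, 0, None) * noise.shot_scale) / noise.shot_scale
            frames[k] = img
        channels[cls] = frames

    return FrameStack(
        channels=channels,
        frame_interval=frame_interval,
        pixel_size=ps,
        source_frames=frame_indices,
    )


def export_truth(tracks: list[GroundTruthTrack], path) -> None:
    """Write ground-truth tracks as a plain CSV track table."""
    truth_table(tracks).to_csv(path, index=False)


def truth_table(tracks: list[GroundTruthTrack]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for f, (x, y) in zip(tr.frames(), tr.positions):
            rows.append((tr.agent_id, tr.agent_class, int(f), float(x), float(y)))
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def load_truth(path) -> list[GroundTruthTrack]:
    df = pd.read_csv(path)
    tracks = []
    for (aid, cls), grp in df.groupby(["agent_id", "class"], sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            GroundTruthTrack(
                agent_id=int(aid),
                agent_class=str(cls),
                born=int(grp["frame"].iloc[0]),
                positions=grp[["x_um", "y_um"]].to_numpy(dtype=float),
            )
        )
    return tracks


def save_stack_tiff(stack, path_prefix) -> dict[str, str]:
    """Write each fluorescence channel as its own multi-page TIFF."""
    paths = {}
    for role, frames in stack.channels.items():
        path = f"{path_prefix}_{role}.tif"
        tifffile.imwrite(path, np.asarray(frames, dtype=np.float32))
        paths[role] = path
    return paths
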