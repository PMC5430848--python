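# chiptrack

Cell tracking and motility analysis for microfluidic immune–tumor
co-culture assays.

`chiptrack` quantifies how motile immune cells (e.g. monocyte-derived
dendritic cells) migrate toward cancer cells inside a two-sided chemotaxis
chip: a central immune chamber connected through arrays of narrow
microgrooves (12 µm wide, 200 µm long "connecting channels") to two
collagen-filled tumor chambers (500 × 1000 µm footprint), one on each side.
From a time-lapse fluorescence movie it produces single-cell trajectories
and compartment-aware motion statistics, so that recruitment toward a
treated tumor space can be compared against an untreated one within the
same device.

The analysis follows the classical unsupervised tracking recipe:

1. **Background elimination** — restrict analysis to the device's culture
   compartments (layout-driven, with an optional temporal-variance
   refinement).
2. **Segmentation** — per frame: Gaussian smoothing, Otsu or fixed
   thresholding within the analysis mask, morphological opening, connected
   components, area filtering, intensity-weighted centroids.
3. **Linking** — minimum-cost one-to-one assignment between consecutive
   frames (squared-displacement cost, hard distance gate, birth/death cost
   = gate²), followed by gap closing with linear interpolation.

Per track and per time window (default 0–24, 24–48, 48–72 h) it then
computes the standard motion parameters:

- path length `L = Σᵢ ‖xᵢ₊₁ − xᵢ‖` and speed `v = L / Δt`;
- pre-/post-channel speed (immune-chamber segment before first channel
  entry / tumor-chamber segment after first infiltration);
- displacement (Euclidean start-to-end, and horizontal `|Δx|` along the
  immune→tumor axis);
- directional persistence `DP = ‖x_end − x_start‖ / L ∈ [0, 1]`
  (1 = straight path, ≈0 = Brownian wandering);
- migrating / infiltrated cell counts per side and window (a cell is
  *migrating* once it reaches a channel or tumor chamber, *infiltrated*
  once it reaches a tumor chamber), and fold increase between conditions;
- immune–cancer interaction times: maximal runs of frames in which an
  immune cell's centroid stays within a circular region of interaction
  (default radius 20 µm) around a cancer cell.

Side-to-side comparisons use the two-tailed unpaired Student's t-test
(pooled variance; Welch available behind a flag).

Because raw assay videos are rarely shareable, the package ships a
first-class synthetic-data generator: agents perform a confined biased
persistent random walk inside the exact device geometry (optionally with
staggered activation and patrolling between cancer cells), near-static
cancer cells jitter in the collagen chambers, and the scene is rendered to
noisy two-channel movies (Gaussian spots, background offset/gradient,
blur, Poisson shot noise). Every pipeline stage is validated against this
known ground truth.

## Worked example

Simulate a 12 h co-culture in which half of 40 immune cells sense a
chemoattractant from the right tumor chamber (bias 0.8), render it to a
noisy movie, and run the full analysis:

```python
from chiptrack import (LinkParams, RunConfig, SimulationConfig, WindowSpec,
                       run_pipeline)

cfg = RunConfig(
    output_dir="demo_run",
    pixel_size=4.0,                      # µm per pixel
    simulation=SimulationConfig(
        n_dcs=40, n_cancer_per_chamber=8,
        n_frames=360, frame_interval=2.0,  # 12 h at 2-min frames
        bias_strength=0.8, bias_side="right", biased_fraction=0.5, seed=0,
    ),
    windows=WindowSpec(windows=((0, 4), (4, 8), (8, 12)), min_frames_in_window=5),
    linking=LinkParams(gate_distance=48.0, gap_frames=2, min_track_length=5),
    seed=0,
)
res = run_pipeline(cfg)
print(res["counts"])
```

Output:

```
 side window  migrating  infiltrated
 left   0-4h          0            0
 left   4-8h          1            1
 left  8-12h          3            2
right   0-4h         31           15
right   4-8h         40           39
right  8-12h         30           30
```

Recruitment is heavily skewed toward the attractant side, and the motion
statistics separate the two populations: mean directional persistence is
0.617 on the biased side versus 0.285 on the unbiased side, pre-channel
speeds are close to the generator's 5 µm/min on both sides (5.05 left,
4.85 right), and 116 interaction events with a mean duration of 17.8 min
are detected around the cancer cells. All tables are also written as CSV
under `demo_run/`, together with a manifest recording the fully-resolved
configuration.

The same pipeline is available from the shell:

```sh
chiptrack simulate --config config.yaml     # movie + ground truth
chiptrack run --config config.yaml          # end-to-end analysis
chiptrack detect / track / metrics / interactions   # stage by stage
```

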