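# Methods

This note documents the models, conventions and numerical choices behind
`chiptrack`, and what the synthetic validation does and does not
demonstrate about real data.

## Device model and coordinates

The chip is modelled in 2D physical coordinates (µm), origin at the
top-left image corner, x rightward, y downward. Compartments are
axis-aligned rectangles laid out symmetrically along x: medium channel |
tumor chamber | connecting channels | immune chamber | connecting channels
| tumor chamber | medium channel. Default dimensions follow the device
this analysis targets: connecting channels 12 µm wide × 200 µm long
(10 per side, evenly spaced), tumor chambers 500 × 1000 µm, immune chamber
1200 µm wide, with a 20 µm outer margin. The 10 µm channel height and
150 µm chamber depth are carried as metadata only: tracking is 2D, which
is the standard compromise for wide-field movies of quasi-planar devices;
z-excursions shorten apparent path lengths slightly and are not corrected.

Rectangles are half-open (`[x0, x1) × [y0, y1)`) so region labels
partition the image exactly. Connecting channels additionally claim both
of their x-boundaries and take classification priority: the shared
immune/channel and channel/tumor edges therefore belong to the channel on
*both* sides of the device, which makes boundary-crossing detection a
deterministic function of the label sequence regardless of travel
direction. Rasterization rounds µm bounds to pixel indices, so
`classify_point` and the rasterized map can disagree only within a
one-pixel border.

Region recognition is layout-driven (the chip geometry is known by
construction); an image-driven refinement (`background_mask(mode="auto")`)
intersects the layout with pixels whose temporal intensity variance
exceeds k× the median in-layout variance (default k = 2), and falls back
to the layout mask with a warning for stacks shorter than 3 frames or
degenerate variance images.

## Synthetic motion model

The generator's purpose is to produce *known* ground truth with the
statistical structure the analysis assumes, not to fit the biology of any
particular cell type.

Immune agents perform a confined biased persistent random walk, advanced
once per frame interval Δt (default 2 min):

- heading: wrapped-normal turn about the previous heading with standard
  deviation `1/√persistence` (persistence 0 draws a fresh uniform heading
  each step); the persistent direction is blended with a unit drift vector
  toward the agent's current target as
  `d = (1−b)·d_persistent + b·d_target`, renormalized, with
  `b = bias_strength ∈ [0, 1]`;
- step length: positive-truncated normal with mean `speed_mean·Δt` and sd
  `speed_sd·Δt` (defaults 5 and 1.5 µm/min — mid-range for fast amoeboid
  leukocyte migration);
- confinement: a step is accepted only if the whole straight segment stays
  inside the culture compartments (immune chamber, channels, tumor
  chambers), checked every ≤3 µm so agents cannot tunnel through walls and
  can enter channels only through their openings. Headings are
  re-drawn (up to 12 attempts) when the segment is blocked — cells turn at
  walls rather than walk into them — with mirrored reflection of the step
  as the fallback for agents pressed against a wall by pure drift. This
  rule keeps the realized step length equal to the sampled one, so the
  cohort's sampled mean speed is an unbiased estimate of `speed_mean`
  (pure mid-step reflection shortens observed frame-to-frame chords and
  biases sampled speed low near walls).

Optional realism features, all off by default:

- `biased_fraction` — only a subpopulation senses the cue (the rest walk
  unbiased), modelling heterogeneous responsiveness;
- `birth_stagger_frames` — agents activate at a uniformly random frame,
  producing the sustained recruitment kinetics seen over multi-day
  recordings rather than a single early wave;
- patrolling — a biased agent's target is an individual cancer cell
  (position jittered by 5 µm); on arriving within
  `patrol_capture_radius` (15 µm) it pauses for a geometrically
  distributed dwell (`patrol_dwell_frames`, mean 7 frames = 14 min at
  default Δt) and then re-targets another cancer cell. This reproduces
  the alternating migration/pausing behaviour of scanning immune cells
  and avoids the unphysical pile-up of all agents on one attractor point.

Cancer agents are near-static: initial positions uniform in their tumor
chamber, per-frame Gaussian jitter (sd 0.3 µm/frame, cumulative, clamped
to the chamber), never leaving it — they stand in for collagen-embedded
tumor cells.

Rendering draws each agent as an isotropic 2D Gaussian spot (sigma = half
its radius: 3.5 µm for immune, 4.5 µm for cancer agents) on the
fluorescence channel of its class; optical blur is folded analytically
into the spot sigma. Noise is a constant background offset, an optional
linear x-gradient, and Poisson shot noise at a configurable photon scale.
Not modelled: photobleaching, z-defocus, cell shape and its changes during
phagocytosis, brightfield contrast.

One root seed drives all randomness (simulation and rendering); analysis
stages are seed-free and deterministic.

## Detection

Per frame, within the analysis mask: Gaussian smoothing (sigma 1 px),
thresholding, morphological opening (radius 1 px), connected components,
area filter (defaults 30–2000 µm², i.e. magnification-independent),
intensity-weighted centroids. Components touching the mask border are kept
and flagged. Touching cells are not split by default (cell density in the
channels is low and the linker's gate tolerates occasional merges); a
watershed flag exists for crowded scenes.

Thresholding is Otsu's split of the *masked* histogram, which makes
detections invariant to adding a constant intensity offset. When a whole
stack is processed, the threshold is computed once per channel from the
pooled masked intensities of ≤24 smoothed frames spread over the movie,
floored at 5 robust sigmas (median + 5·1.4826·MAD) above background. The
pooling stabilizes frames with few cells, whose per-frame histogram is
essentially unimodal noise; the floor makes a channel with no real
foreground yield no detections instead of an arbitrary noise split. Pixel
index i is taken to sample physical position (i + 0.5)·pixel_size, which
makes rendering and centroid extraction agree to well under half a pixel
on clean spots.

## Linking

Frame-to-frame linking solves the standard linear-assignment formulation:
cost of a candidate link is its squared displacement; pairs farther apart
than `gate_distance` are forbidden; every detection has a birth/death
alternative costing `gate_distance²`. The augmented square matrix is
solved exactly (Jonker–Volgenant), so the total cost provably equals the
brute-force minimum over all gated partial matchings — this is checked
against an enumeration oracle in the tests. Gap closing then greedily
merges, in ascending squared-distance order, track ends with later track
starts of the same class within `gap_frames` missed frames and
`gate_distance × gap` distance, filling the gap by linear interpolation
(flagged in the output). Tracks shorter than `min_track_length` are
dropped.

Defaults: gate 48 µm per frame interval (3× the expected step of an
8 µm/min cell at 2-min frames), gap 2 frames, minimum length 5 frames.
These are declared package defaults, not values inferred from any
particular instrument; all are config entries. Constant-velocity motion
prediction exists behind a flag and is off by default. Frame-to-frame
assignment plus gap closing was chosen over global multi-frame
optimization because it is oracle-verifiable and adequate at the cell
densities this assay produces; it will fragment tracks in very crowded
scenes, which inflates count-based read-outs on both sides of the device
symmetrically.

## Motion parameters and windows

All metrics are computed on trajectory polylines in µm. Directional
persistence is displacement over path length; by the triangle inequality
it lies in [0, 1], reaching 1 exactly on monotone collinear paths. Time
windows are half-open in hours (default 0–24, 24–48, 48–72); a track
contributes one metrics row per window, computed on the sub-segment of
frames inside the window, if that sub-segment has at least
`min_frames_in_window` (default 5) points — too-short segments make DP and
speed estimates meaningless. Count read-outs assign a cell to the window
containing its qualifying *event* frame (first channel-or-tumor entry for
migrating, first tumor entry for infiltrated), once per category; a cell
that re-enters a channel after infiltrating stays counted once and is
flagged (`reverse_crossing`) but not aggregated.

Displacement is emitted in both modes because the field uses both: the
horizontal mode (|Δx| along the immune→tumor axis) is the default
read-out, the Euclidean mode is also reported. Pre-channel speed uses
immune-chamber points strictly before the first channel entry;
post-channel speed uses tumor-chamber points from the first infiltration
on; frames inside a channel contribute to neither (only the two chamber
speeds are defined read-outs).

A metrics row's `side` is the side the cell migrated to; cells that never
left the immune chamber are sided by the device half (segment mean x
relative to the immune-chamber centerline) when a layout is supplied —
the convention used when comparing chamber-resident cells "next to" each
tumor space in a two-sided competition assay.

## Interactions

An interaction event is a maximal run of frames in which an immune cell's
centroid lies within `radius` of a cancer cell's centroid inside a tumor
chamber; runs separated by at most `gap_tolerance` frames (default 1,
tolerating single missed detections) are merged. Duration counts both
endpoints: `(end − start + 1) × frame_interval`. The default radius of
20 µm ≈ immune radius + cancer radius + 4 µm margin is a declared,
logged configuration entry — centroid distance is a proxy; true
membrane-to-membrane contact would require segmentation outlines, which
is out of scope. An immune cell inside two interaction regions yields one
event per cancer cell. Phagocytosis (engulfment vs. contact) is not
classified.

## Statistics

Condition comparisons use the classical equal-variance two-sample t-test,
two-sided, significant at p ≤ 0.05; Welch's form is available via
`welch=True`. Group summaries report n, mean, sd and sem per side and
window at the per-cell level (in a single synthetic run there is no
experiment-level replication to aggregate over).

## Validation scale and what it shows

The test suite and `scripts/acceptance.py` validate the pipeline on
synthetic data at desk scale, chosen so the full suite runs in a few
minutes on one CPU:

- closed-form metric checks on hand-constructed 3-point paths;
- linking optimality on 120 random instances with ≤7 detections per frame
  against exhaustive enumeration;
- detection fidelity on rendered movies of 60 well-separated cells
  (70 µm spacing, peak SNR ≫ 5): recall/precision ≥ 0.95 and centroid
  RMSE ≤ 0.5 px (measured ≈ 0.1 px on noiseless spots);
- parameter recovery on cohorts of 200 tracks × 100 frames at speeds 2, 5
  and 8 µm/min (recovered within 3 standard errors) and DP strictly
  increasing over bias 0 → 0.5 → 1;
- exact interaction timing on scripted dwell schedules;
- the standard end-to-end fixture: 100 immune cells (half biased at 0.8
  toward the right chamber, half unbiased), 10 cancer cells per chamber,
  72 h of ground truth at 2-min frames, rendered every 3rd frame (6-min
  stack) at 4 µm/px. The pipeline must report strictly more migrating and
  infiltrated cells and higher mean windowed DP on the biased side in
  every 24 h window; this ordering was verified on several seeds before
  the test seed was fixed;
- t-test calibration: hand-checked statistic on a toy pair and empirical
  type-I error within [0.03, 0.07] over 2000 null simulations.

Passing these tests shows the *pipeline* is correct and well calibrated on
movies whose generative model it assumes: Gaussian-spot cells, known
geometry, modest density. It does not certify performance on real
recordings with uneven illumination, debris, cell-shape changes, focus
drift, or densities high enough to make merges common — on such data the
segmentation and gating parameters need tuning, and count read-outs
should be interpreted as lower bounds on tracking quality.

## Known limitations

- 2D analysis of a quasi-3D device; vertical motion is invisible.
- No split/merge handling in the linker; crowded chambers fragment tracks.
- The interaction radius is a global constant, not per-cell-size.
- The synthetic generator's motion model is phenomenological; its
  parameters (speed, persistence, bias) are calibration knobs, not
  measurements of any cell type.
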