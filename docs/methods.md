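# Methods

`pseudoislet3d` quantifies multi-channel 3D fluorescence z-stacks of
pseudoislets — in-vitro aggregates of alpha (Alpha TC1), beta-like
(INS1E) and endothelial (HUVEC) cells that mimic a pancreatic islet —
and benchmarks four segmentation strategies modelled on widely used
image-analysis software against exact synthetic ground truth. This note
documents the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic benchmark does and does not
demonstrate about real data.

## Coordinate and unit conventions

Voxel indices are 0-based `(z, y, x)`; a voxel's physical position is
its centre. All physical lengths are micrometres and convert to voxel
counts only through the two calibration factors of `VoxelGeometry`
(lateral pixel size, axial step), rounding half-up per axis. Parameters
that published pipelines state in pixels (e.g. a 50-pixel rolling ball)
carry an explicit `px` unit tag and bypass calibration; µm-denominated
parameters (e.g. a 27 µm rolling ball) are converted per axis, because
spinning-disk stacks are anisotropic. Configuration files are flat
key:value text; unknown keys are errors, since parameter fidelity is
the point of a preset.

## The four presets

Each preset fixes the documented parameter set of one software
workflow and executes a fixed operator chain per channel:

| preset | chain (nuclei / cytoplasm channels) |
|---|---|
| `fiji` | rolling-ball subtraction (50 px) → threshold → 3D connected components (26-connectivity) → voxel filter > 250 |
| `cellprofiler` | rescale to [0, 1] → median filter (5³) → adaptive two-class Otsu → components → measurement |
| `ga3` | rolling ball (27 µm) → z-intensity equalisation → Laplacian of Gaussian (σ = 2 px) → threshold → components; 60 % core volume |
| `imaris` | Gaussian background subtraction (60 µm; 20 µm for the collagen channel) → z normalisation → 6 µm spot detection (nuclei) or surfaces (0.6 µm smoothness, 16 µm background diameter, 8 µm split, ≥ 353 µm² slice area) for cytoplasm; 80 % core volume; 0 µm contact distance |

Two interpretation choices deserve mention. The original workflows set
intensity thresholds manually per dataset; an automated benchmark needs
a deterministic stand-in, so presets whose threshold is unspecified use
a global two-class Otsu (`manual_threshold` remains available for
per-dataset values). And the GA3 "Gaussian LaPlace, power 2.0" carries
no unit in the source material; it is implemented as a
Laplacian-of-Gaussian with σ = 2 pixels, sign-flipped so blobs are
positive, and this is a configurable assumption (`log_sigma`).

### Preprocessing operators

*Rolling ball* is applied per z-slice (the classic implementation is
slice-based) as a grayscale opening with a non-flat ball-shaped
element; output is input minus background, clipped at zero. Radii up to
16 px use the exact opening; larger radii — including both published
values at desk-scale image sizes — use the standard shrink/restore
strategy (min-pool and downscale by ≈ radius/8, roll the ball at the
reduced radius, upscale, cap at the input). The background estimate at
such radii carries no fine detail, so the approximation error is well
below the operator's intended effect.

*Z equalisation* rescales each slice multiplicatively so its robust
foreground centre (median of voxels above the slice's own Otsu
threshold) matches the brightest slice, compensating depth-dependent
signal loss. Slices with no foreground are left unscaled and flagged in
a per-slice report. The operator is idempotent up to the re-estimation
of per-slice thresholds (tested at 2 %).

*Gaussian background subtraction* (the Imaris convention of removing
structures wider than a length L) subtracts a Gaussian blur with
σ = L/2 per axis. Very wide kernels (σ > 8 voxels) are evaluated on a
downscaled copy and resampled, which is exact to interpolation order
for a background that by construction has no content at the fine
scale. A length below one voxel would subtract the image from itself;
that degenerate case warns and returns zeros.

*Laplacian of Gaussian* subtracts each slice's mean before filtering,
making the response exactly invariant to intensity offsets (the
truncated discrete kernel otherwise leaks a small DC term).

### Segmentation operators

*Adaptive Otsu* computes a per-block threshold on a block grid,
interpolates linearly between block centres, and clamps each block to
0.7–1.5× the global Otsu threshold — the bound CellProfiler applies so
that background-only blocks cannot manufacture foreground. Otsu ties
break toward the lower threshold for reproducibility.

*Size filtering* uses two deliberately different comparison rules,
matching how the two source workflows state them: the voxel-count rule
is strict (a "filter size > 250" removes an object of exactly 250
voxels), while the slice-area rule is inclusive (filtering "below
353 µm²" keeps an object at exactly 353 µm²). The 353 µm² figure is an
area in a 3D context, implemented as the object's maximum single-slice
cross-section.

*Watershed splitting* seeds a marker-controlled watershed with local
maxima of the µm-calibrated Euclidean distance transform. Seeds are
deduplicated at half the split diameter: two objects of the stated
diameter fused by a 25 % overlap (centres ~0.75 diameters apart) then
still carry separate seeds, which is the behaviour the
"split touching objects of diameter d" control produces in the emulated
software. Every connected component keeps at least one seed, so
splitting never decreases the object count. Local maxima are found with
a separable box filter inscribed in the suppression ball followed by
exact Euclidean pruning; this is algebraically equivalent to the dense
ellipsoidal neighbourhood but runs in linear time.

*Spot detection* (Imaris-style nuclei) computes a scale-matched negated
LoG response (σ = diameter/(2√2), anisotropy-corrected per axis), takes
local maxima, suppresses duplicates within half a diameter keeping the
stronger response, and applies a quality threshold. The automatic
quality mode emulates a histogram-based filter: Otsu over the candidate
responses, with a unimodality guard — when every candidate lies within
a factor of two of the strongest response there is only one class, and
bisecting it would discard genuine spots, so all candidates pass. The
guard matters exactly in the clean limit, where no background ripple
exists to form the second histogram class.

## Core/mantle partition

Both region-capable presets split the spheroid volumetrically: the core
is the deepest fraction f of the whole-spheroid mask (f = 0.60 for the
GA3 preset, 0.80 for Imaris), the mantle the remaining shell. Discrete
erosion steps cannot hit a target fraction on small masks, so the
partition thresholds the µm-calibrated Euclidean distance transform at
the distance value whose achieved fraction is closest to the target,
searching all distinct distances (ties in the transform make a plain
quantile index unreliable). On masks of realistic size the achieved
fraction lands within the declared ±2 % of the target; the erosion is
physically calibrated, so the shell has uniform µm thickness despite
anisotropic voxels.

The whole-spheroid mask comes from the nuclei channel: global Otsu,
ball closing, per-slice hole filling, largest component. The closing
radius defaults to 14 µm (about two cell diameters): it must bridge
both inter-nuclear gaps and the surface dips between the outermost
nuclei, and at the packing density the simulator can realise, a smaller
ball leaves a scalloped envelope well below the aggregate's nominal
volume. The ball closing is computed with two distance transforms
(equivalent to dilate-erode with a ball, but linear-time).

A second, layer-based convention (`layer_based_regions`) emulates
manual scoring: a cell is mantle if its centroid lies within
n layers × cell diameter of the mask surface. The benchmark reports
both references.

## Cell–ECM co-localization

Object-based, not pixel-based: a cell (child) interacts with the
collagen-IV network (parent) iff its minimum surface-to-surface
distance is at most a cutoff, measured between voxel centres via the
distance transform of the parent foreground. At the published cutoff of
0 µm the criterion reduces to voxel overlap or — by default, and
configurable — 26-adjacency, since touching is the boundary case of
"< 0 µm distance" overlap scoring.

## The simulator

`SimulationConfig` defaults encode the study conditions: 1500 cells at
an Alpha TC1 : INS1E : HUVEC ratio of 1:9:5 (largest-remainder
apportionment, seeded shuffle over positions), 6 µm-diameter nuclei in
7 µm cells, packed to touching (centre separation ≥ 0.8 × cell
diameter) inside a 55 µm-radius aggregate — consistent with a ~110 µm
pseudoislet imaged over a 0–90 µm z-range. Placement is dart-throwing
with a spatial hash, falling back to repulsive relaxation, erroring
with the maximum feasible count when the request exceeds an effective
packing of 0.45. Everything is deterministic given the seed.

Rendering sums spherical nucleus kernels for all cells into the nuclei
channel and cytoplasmic shells (nucleus-to-cell radius) into the INS1E
and alpha channels for cells of that type only; HUVECs carry no
cytoplasm label, so nucleus counts exceed labelled-cell counts as in
the real assay. The collagen channel holds random polyline tubes
(default 40 fibres of 0.5 µm radius) confined to the aggregate, and the
ground-truth contact flag is exact by construction (cell sphere
contains a fibre voxel centre). Each channel is then attenuated by
exp(−depth/attenuation length) (default 50 µm, emulating the signal
loss deep in a scattering aggregate), blurred with an anisotropic
Gaussian PSF (σ = 0.4 µm lateral, 1.0 µm axial), offset by a smooth
z-constant polynomial background (10 % of peak) and corrupted by
Poisson shot noise (200 photons per intensity unit) plus Gaussian read
noise (σ = 1 %).

With two peripheral cell layers defining the ground-truth mantle, a
dense ~55 µm aggregate places roughly half its cells in the mantle —
considerably more than the ~20 % a by-eye estimate suggests for real
pseudoislets. The two are only reconcilable for aggregates far larger
than 1500 touching cells can form; the simulator keeps the composition
and density faithful and leaves `mantle_layers` as an explicit knob.

What the simulator does **not** model: rigorous optics (no
Gibson–Lanni PSF, no spectral bleed-through), microwell-wall
autofluorescence, cell shape irregularity, chromatin texture, or
intensity variation between cells of one type. Its cytoplasm "shells"
are cleaner and hollower than real mNeonGreen2 signal, which is why
surface-style segmentation of the synthetic INS1E channel is harsher
than on real data (see Limitations). Passing the benchmark therefore
demonstrates correct mechanics of each operator chain under controlled
artifacts — not that a preset would achieve the same accuracy on real
microscopy.

## The benchmark

The comparison metric is the relative change,
100 × (count − reference)/reference, i.e. the percent over/under-
estimation against a reference count; on synthetic data the exact
ground truth plays the reference role that manual counting plays on
real data (the manual double-count scan is not emulated — truth is
exact by construction). Detections are matched to truth centres by a
Hungarian assignment restricted to pairs within one nucleus diameter
(6 µm); mean relative changes are signed.

Two predefined regimes run at a 128 × 128 × 100-voxel grid
(0.65 µm × 0.8 µm voxels), sized so a 4-preset × 9-dataset benchmark
completes in minutes on one CPU:

* **easy** — 200 cells, separation ≥ one cell diameter, no attenuation,
  no PSF, no background, no noise. Any sound pipeline should recover
  the nucleus count within ±5 %.
* **hard** — 200 touching cells (separation ≥ 0.8 diameters), 45 µm
  attenuation length, PSF, background and noise as in the defaults.
  The presets diverge strongly here (component-labelling chains merge
  touching nuclei; watershed/spot chains hold up), and per-preset
  |relative change| is never smaller than in the easy regime.

The LoG-based GA3 chain additionally applies a single-step binary
opening after thresholding, the standard cleanup that removes
few-voxel noise speckles which an automatic global threshold lets
through on noisy data (the original workflow avoided these by manual
per-dataset thresholds).

## Known limitations

* The Imaris-style 353 µm² slice-area filter exceeds the maximal
  cross-section (~38 µm²) of a single 7 µm synthetic cell, so at
  synthetic scale the imaris preset reports zero INS1E surfaces — the
  published value presupposes the large merged masks real INS1E signal
  produces. The filter's cut-off itself is verified directly by a
  sweep of object sizes.
* Adaptive-Otsu chains fragment hollow cytoplasm shells; synthetic
  INS1E counts for the cellprofiler preset are noisy in both
  directions.
* The automatic thresholds stand in for per-dataset manual tuning;
  absolute hard-regime accuracies therefore characterise the automated
  chains, not the hand-tuned originals.
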