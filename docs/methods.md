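# Methods

This note documents the models, numerical choices and limitations behind
`spimscreen`. It is written for someone who wants to know *why* the package
does what it does, not just how to call it.

## The imaging problem being modelled

A dual-view inverted light-sheet microscope (diSPIM geometry) acquires two
orthogonal stacks, view A and view B, of the same H2B-labelled sample. Each
view has good lateral but poor axial resolution; because the two optical
axes are perpendicular, the blur directions are complementary and the two
views can be fused into a near-isotropic volume. Calibration comes from
fluorescent beads embedded in gel at a dedicated plate position: the beads
give (i) the affine transform mapping view-B coordinates into the view-A
frame, (ii) an empirical PSF per view, and (iii) the slow global stage
drift over a time lapse. The calibration estimated at the bead position is
transferred to all sample positions acquired at the same timepoint.

Downstream, nuclei are segmented in the fused volumes, classified into
cell-cycle phases from their chromatin morphology, assembled into spheroid
time series (counts, volumes, shapes, growth rates, migration speeds,
phase-transition bookkeeping), and finally summarized as a samples ×
features phenotype matrix that is rank-clustered into phenotype groups.

## Synthetic scenes as ground truth

Real screens of this kind produce terabytes of stacks that cannot ship with
a package, so every stage here is driven and verified by a synthetic scene
generator (`spimscreen.scene`). Its defaults are the study conditions the
package targets:

| parameter | default | meaning |
|---|---|---|
| `cycle_length` | 1260 min | ~21 h MCF10A-like cell cycle |
| `phase_durations` | prophase 11.3, metaphase 15.1, anaphase 40.3 min | mitotic phase lengths; interphase is the remainder (1193.3 min) |
| `frame_interval` | 5 min | acquisition cadence |
| `n_frames` | 289 | 24 h time lapse |
| `nucleus_radius_mean/sd` | 4.0 / 0.4 µm | H2B-filled nucleus size |
| `spheroid_packing_distance` | 12 µm | centre-to-centre spacing (~1.5 nucleus diameters, leaving cytoplasm between nuclei) |
| `random_walk_sd` | 0.1 µm/frame | small nucleus jitter, so tracking is non-trivial |
| voxel (render) | 0.5 µm isotropic | "isotropic-equivalent" desk-scale grid; the camera's native 0.1625 µm/px and 0.5 µm slice spacing are carried as metadata and supported for full-scale grids |
| PSF σ (per view) | 0.3 µm lateral, 1.0 µm axial | Gaussian optics model |
| noise | Poisson shot noise at `photon_scale`=200 + Gaussian read noise σ=2 counts, background 5 counts | a realistic sCMOS light-sheet noise model (SNR ~14 at nominal chromatin density) |

The mitotic phase durations are exactly the values implied by the control
phase fractions of the screen this package models (fraction × cycle
length), so the stationary occupancy of the generator reproduces those
fractions by construction.

### Phase morphologies

The generator encodes chromatin appearance per phase as minimal geometric
archetypes that a texture or CNN classifier can separate — not as
photorealistic chromatin:

* **interphase** — soft-edged sphere, mild large-scale texture
  (amplitude 0.15, scale 2.2 µm);
* **prophase** — same envelope with strong condensed speckles
  (amplitude 1.4, scale 1.5 µm);
* **metaphase** — dense flattened plate (half-thickness 0.35 r, radius
  1.15 r) perpendicular to the division axis, fine striations (0.25/0.6 µm)
  that largely blur away, leaving a bright smooth bar/disc;
* **anaphase** — two lobes (radius 0.72 r) separating along the division
  axis from 0.35 r to 0.8 r centre distance, joined by a dim midzone
  bridge, moderate coarse texture.

Texture fields are sampled in world space from a per-nucleus seed, so both
views see the same chromatin pattern. The anaphase separation is capped at
0.8 r so that one anaphase nucleus remains a single connected segment under
the segmentation's erosion-splitting rule (see below); divisions then place
the two children a packing distance apart.

### Population dynamics and the occupancy law

Nuclei carry asynchronous cycle clocks (initial ages uniform over the
cycle). Two modes exist:

* `divisions=True` (default): a wrapping clock replaces the nucleus by two
  children placed along its division axis. Use this for growth, tracking
  and lineage work.
* `divisions=False` ("renewal"): the clock wraps in place and the
  population stays constant.

The distinction matters for phase-fraction accounting. Only in the renewal
mode does the expected fraction of nucleus-frames in phase *p* equal
duration(*p*)/cycle — the closed-form occupancy law. In a *growing*
population the age structure skews young (children are born into
interphase), and the mitotic fractions fall strictly below duration/cycle
(by a factor approaching ln 2 ≈ 0.69 for steady exponential growth). The
control fractions this package reproduces are consistent with the
stationary duration/cycle accounting, so the end-to-end occupancy
benchmark simulates the control population in renewal mode. This is a
deliberate modelling choice, documented here because it is easy to get
silently wrong in either direction.

## Bead calibration

* **Detection**: local maxima above median + `snr_threshold` × MAD-noise,
  refined to sub-voxel positions by intensity-weighted centroids in a
  1.5 µm window; of any pair closer than `min_separation` the brighter
  survives. On rendered beads at SNR 20 localization error is well under
  0.3 voxel.
* **Registration**: iterated nearest-neighbour matching (initialized from
  the nominal 90° view rotation, matches > 5 µm rejected) alternating with
  a 12-dof least-squares affine fit until the assignment is stable. A full
  affine subsumes the rigid truth and absorbs calibration scale errors.
  RANSAC is unnecessary — bead fields are sparse and clean. The stored
  residual is the RMS distance over final correspondences.
* **PSF**: background-subtracted windows around isolated beads (no
  neighbour within 2 × radius), sampled at the sub-voxel centroid,
  averaged, clipped at zero, normalized to unit sum.
* **Drift**: per-axis median of bead displacements relative to frame 0,
  with nearest-neighbour gating; frames without matches inherit the
  previous offset. The median makes a single misbehaving bead harmless.

## Fusion and deconvolution

View B is pulled back onto the isotropic reference grid by trilinear
interpolation through the estimated transform; voxels outside the source
footprint are zero and recorded in a validity mask. Fusion is alternating
joint Richardson–Lucy: initialize with the mean of the two registered
views, then per iteration apply the multiplicative RL update for view A
and then view B, each masked to its validity region (`n_iter=10`,
`epsilon=1e-6` by default). `n_iter=0` returns the plain mean
(registration-only fusion). The per-view Poisson data-fit terms are logged
per iteration; on consistent data the combined objective is
non-increasing, and a two-view bead blurred along complementary axes fuses
to a near-isotropic spot — the operational meaning of "isotropic
resolution".

The end-to-end occupancy run uses registration-only fusion (`n_iter=0`):
phase classification operates on morphology that is robust to the residual
blur, and skipping deconvolution keeps the full 150-frame pipeline run in
the minutes range on one CPU. Deconvolution quality is validated
separately by the RL property tests.

## Segmentation and features

Gaussian smoothing (σ 0.5 µm) → global Otsu threshold → 26-connected
components → erosion-based splitting → minimum-size filter (30 µm³) →
relabelling. Splitting erodes each component step by step (6-connected
structuring element) up to `split_erosion_radius` (default 1.5 µm = 3
steps at 0.5 µm voxels) and keeps the erosion level that exposes the most
cores of ≥ 5 voxels; the cores seed a watershed on the negated distance
transform, constrained to the component. The depth bound is what separates
genuinely touching interphase neighbours (thin necks, split after 1–3
steps) from the thick-necked dumbbell of a single anaphase nucleus (which
must *not* split — that would double-count anaphase). This is also why the
generator caps anaphase lobe separation.

Geometry: volume = voxel count × voxel volume; centroids intensity
weighted; intensities raw. Texture: 13 Haralick statistics (angular second
moment, contrast, correlation, variance, inverse difference moment, sum
average/variance/entropy, entropy, difference variance/entropy, and the
two information measures of correlation) from symmetric gray-level
co-occurrence matrices accumulated over the 13 unique 3D unit offsets,
averaged over offsets. Intensities are min–max quantized to 32 levels
*per segment*, which makes the features invariant to affine intensity
rescaling (illumination robustness). Segments under 8 voxels get NaN
features and a log entry. Entropies use log₂; a segment with zero
intensity spread has ASM 1, contrast 0, entropy 0, and correlation is
defined as 0 where either marginal is degenerate.

## Phase classification

Two classifiers mirror the screen's model comparison:

* **Random forest** on the per-nucleus Haralick vectors: 200 trees, √p
  features per split, balanced class weights, fixed seed.
* **Slice CNN**: 2D patches are cut from each segmented nucleus in all
  three orientations (XY/XZ/YZ). The segment's bounding box is expanded to
  a cube so aspect ratio survives resizing; each plane intersecting the
  segment gives one patch, masked to the segment, min–max normalized and
  resized to 32×32. The network is a compact VGG-style numpy CNN — three
  3×3 conv + ReLU + 2×2 max-pool blocks (16→32→64 channels), one dense
  layer of 128, softmax — trained with Adam on cross-entropy (8 epochs by
  default) with 90° rotation/flip augmentation and a stepped learning-rate
  decay. Training is seeded and single-process, hence reproducible. A 32×32 input (rather
  than a larger patch) fully resolves ~16-voxel nuclei and keeps CPU
  training in the minutes range.
* **Voting**: the per-slice probabilities of a nucleus are summed; the
  class with the largest sum wins (ties resolve to the earliest class in
  the declared order, interphase first). Aggregated probabilities are the
  normalized sums.

Holdout accuracy is measured on a stratified 90/10 split at the *nucleus*
level (all slices of one nucleus stay on one side), so near-duplicate
slices cannot inflate it. The 6-class variant (adding macronuclei and
apoptotic condensed DNA for the 2D pre-screen) is the same architecture
with six outputs.

## Spheroid time series

Segments are clustered into spheroids by single-linkage agglomeration cut
at 25 µm (~2 nucleus diameters), with ids kept stable across frames by
matching cluster centres to the previous frame. Tracking is greedy mutual
nearest neighbour with a 10 µm gate per 5-min frame; new nuclei appearing
near a just-ended track record it as their parent (one-generation division
links). Migration speed is the per-spheroid median over all track steps.
Radial positions are distances to the mean of member centroids. Transition
bookkeeping flags any consecutive pair of phase calls outside
{I→P, P→M, M→A, A→I, A→division} as improper; totals are reported both as
event counts and as affected-nucleus counts. Growth rates are lowess
(span 1/3, 3 robustifying iterations, delta = 0.01 × series range)
followed by first differences; lowess reproduces straight lines exactly
and the pipeline recovers the doubling time of simulated clonal expansions
within 15%. Shape descriptors: sphericity = π^⅓(6V)^⅔/A with the surface
area from a marching-cubes mesh; convexity = voxel count over the voxel
count of the voxelized convex hull (numerator and denominator share the
discretization, so a digital ball scores ~1 and convexity ≤ 1 exactly);
compactness = V over the volume of the sphere centred at the centroid with
radius reaching the farthest voxel centre (a tight approximation of the
minimal enclosing sphere for blob-like shapes).

## Phenotype profiles

Feature tables are concatenated, centred and scaled per column; constant
or all-missing columns are dropped with a warning, and per-plate exclusion
masks blank features that are unreliable on one plate. Clustering replaces
each column by its ranks across samples (average ranks on ties), takes
Euclidean distances between rank rows and applies complete-linkage
agglomeration; the tree is cut at the requested number of groups. Ranking
per column is the default reading of "rank-based"; a whole-matrix rank
mode is available behind `rank_mode="global"` since either reading is
defensible. Rank clustering is invariant under strictly monotone
per-feature distortions and fully deterministic.

## Screen layout and pre-screen

Spot grids follow the 1536-well positions (2.25 mm pitch), 40 columns × 8
rows = 320 spots, samples on contiguous 2×4 subarrays. Acquisition
accounting is exact integer arithmetic (40 positions × 1200 slices × 2
views = 96,000 pre-screen images; 2·1024²·260·2 B ≈ 1.09 GB raw per
position-timepoint). Pre-screen selection excludes small (< 2×10⁴ µm³),
flat (flatness > 3) and elongated (aspect > 2.5) clusters and takes the
largest-Z survivors per condition; the size/shape thresholds are this
package's defaults — the original screen states the rules but not the
numbers.

## Benchmark problem sizes

The default 4-class morphology benchmark renders 800 nuclei per class on
36³ mini-grids and extracts 3 central slices per orientation (9 patches
per nucleus, 28,800 slices). The end-to-end occupancy run uses 64 nuclei ×
150 frames at 5-min cadence on a 128³ grid at 0.5 µm — sizes chosen so the
full suite runs on a single desktop CPU core in well under half an hour
while keeping sampling error a small fraction of the tolerances (with 64
renewing nuclei over 150 frames the binomial error on the anaphase
fraction is ~0.3 percentage points).

## Known limitations

* Morphology archetypes are caricatures: no chromatin substructure,
  nucleoli, stripe/shadow light-sheet artifacts or depth-dependent
  scattering. Classifier accuracies on this benchmark say the pipeline
  wiring is correct, not that the trained models transfer to real data.
* The Gaussian PSF model omits diffraction side lobes and light-sheet
  tilt; the affine registration cannot absorb field-dependent distortions.
* Tracking links one generation of parents/children only; no full lineage
  trees.
* The minimal-enclosing-sphere radius is approximated from the centroid,
  which can underestimate compactness for strongly asymmetric shapes.
* Phase fractions from *growing* populations are systematically below
  duration/cycle (see the occupancy discussion); consumers comparing
  fractions across conditions should hold the population mode fixed.
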