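# Methods

This note documents the models, procedures and numerical choices implemented
in `canopyseg`, in the package's own terms: what is computed, under which
assumptions, and where the design was genuinely open.

## Problem setting

The package maps the canopies of a single target plant class (a species or a
vegetation community) in very-high-resolution UAV orthoimagery.  At
centimetre ground sampling distances, plant classes are distinguished mostly
by their spatial texture — crown speckle, branch patterning, within-canopy
gaps — rather than by mean color, and a photogrammetric surface model adds
canopy-height relief as a second, geometric cue.  Per-pixel classifiers
cannot exploit either; a fully convolutional encoder–decoder can.  The
workflow is: delineated reference polygons are rasterized to a binary mask;
fixed-size tiles of predictors (RGB + normalized DEM) and mask are sampled on
a regular grid; a U-net is trained with dice loss; accuracy is reported
stratified by target-class cover; and the trained model is applied tile-wise
across an extract and merged into one georeferenced segmentation map.

## Synthetic scenes

UAV campaigns of this kind are rarely redistributable, so the package ships a
scene generator that reproduces the *statistics the method exploits* rather
than photographic realism:

* **Texture-coded classes.** Both classes are band-limited Gaussian speckle
  with class-specific correlation length (grain), contrast and anisotropy,
  rendered around near-identical mean colors (the generator *rejects* configs
  whose class means differ by more than a tolerance, 6 digital numbers by
  default).  A pixel-wise linear classifier on RGB is therefore near chance,
  while a local-variance statistic at the speckle scale separates the classes
  — both properties are asserted by tests.
* **Canopy geometry.** Canopies are star-convex blobs (radial harmonics on a
  circle, amplitudes ≤ 0.25/k for harmonics k = 2…6) with radii drawn from a
  configurable range that deliberately extends below the tile scale, since
  small canopies are the known hard case.
* **Cast shadow.** Shadow has three parts, all darkened by a configurable
  multiplier (default 0.25): a self-shadowed crescent inside each canopy on
  the fixed down-sun side — the canopy pixels whose distance-to-edge lies
  below the quantile that makes the crescent ≈ `shadow_fraction` of the
  canopy area (default 0.15) — the canopy silhouette projected
  `shadow_length_m` (default 2 m ≈ canopy height / tan of sun elevation)
  onto the adjacent ground, and elongated patches thrown by taller off-class
  vegetation (`shadow_occluders`, default 8) that land on canopy interiors
  and open ground alike.  The balance matters: if dark pixels were mostly
  canopy, darkness would be a class cue and a model would *benefit* from
  shadow.  With the default geometry most shadow falls on ground
  (P(canopy | dark) ≈ 0.43), darkness is ambiguous and crushes the texture
  signal, which is precisely the regime in which very dark cast shadow
  produces false negatives in real flights.
* **Sparse canopies.** A configurable fraction of canopies is rendered
  dot-patterned (target texture interleaved with ground texture at ~45%
  cover) while the reference polygon still delineates the full extent,
  emulating sparse shrub canopies.  Default 0 — the headline synthetic
  condition uses compact canopies.
* **DEM.** Smooth sloping terrain (planar trend, default 4 m corner-to-corner,
  plus large-scale roughness of ±1.5 m) with canopy-height bumps (default
  1.8 m) that taper linearly over the outer 0.5 m of each canopy and carry
  ±0.35 m of correlated surface noise, emulating photogrammetric canopy
  models: height is informative but neither sharp at edges nor noise-free.
  Inside shadow, dense image matching has little to work with, so the
  generator attenuates canopy relief there (70% lost by default) and adds
  extra reconstruction noise (±0.3 m) — in deep shadow *both* the radiometric
  and the geometric cue degrade, as in real photogrammetric products.

Default scene: 60 m × 60 m at 3 cm GSD (2000 × 2000 px), 30 canopies with
radii 1.5–6 m (≈ 25–35% scene cover).  What passing tests on these scenes do
**not** show: robustness to registration error between image and DEM, to
radiometric seams between flight lines, to delineation errors in the
reference polygons, or to classes whose texture contrast is weaker than the
configured one.  Scenes use a placeholder metric UTM CRS; all distances are
metres.

## Tiling and data splits

Candidate tile origins form a regular grid with 5 m spacing anchored at the
scene's upper-left pixel (a random grid offset is available).  With 128-px
tiles at 3 cm GSD (3.84 m) the spacing guarantees non-overlap; sampling
refuses to proceed when `grid_spacing_m < tile_px × gsd`.  "Randomly sampled
using a regular grid" is read as: the grid defines candidates, a seeded
uniform subset of up to `max_tiles` is drawn.  Tiles crossing the scene edge
are discarded.  Each tile stacks R, G, B scaled by 1/255 and the DEM
normalized *within the tile window* to 0–255 and then scaled by the same
1/255, so all four predictor channels live in [0, 1]; per-window
normalization (rather than per-scene) is what actually removes terrain trend
on sloping ground, and a per-scene switch exists for flat sites.  Splits are
66.6% training pool / 33.4% validation, with 20% of the pool held off for the
per-epoch checkpoint metric; assignment is per-tile, seeded and uniform.  No
spatial blocking is applied — neighbouring tiles can land in different
partitions, which on strongly autocorrelated scenes makes validation
slightly optimistic; a blocked split is the obvious extension.

## Augmentation

Per training tile and step, a transform is drawn uniformly: shear 0–0.2 rad,
rotation a multiple of 20° (including 0°), per-axis shift up to 15% of the
tile edge with random sign, and independent horizontal/vertical flips.
Predictor channels are warped bilinearly, the mask by nearest neighbour (so
labels stay {0,1}), both through the identical affine matrix about the tile
center; out-of-frame pixels are filled by reflection.  Augmentation runs on
the fly; nothing is pre-materialized.

## Architecture

The U-net has 5 resolution levels: two 3×3 same-padding convolutions with
ReLU per level, 2×2 max pooling between levels, feature depth doubling from
`base_filters` (default 16) at level 1 to 16× at the bottleneck (8 × 8 px for
128-px tiles), a mirrored decoder of 2×2 transposed convolutions with skip
concatenation, and a 1×1 convolution with sigmoid producing per-pixel
presence probabilities at the input resolution.  Forward and backward passes
are implemented directly in NumPy (shifted-GEMM convolutions in float32), so
training runs on a single CPU with no framework dependency.  Weights use
fan-in-scaled He initialization from a seeded generator.  The output bias is
initialized to −1.1 (the logit of a ≈25% target-class prior): starting from
a background-dominated prediction prevents the early collapse into an
all-ones prediction that the dice loss otherwise favours while the network
is still undiscriminating.  No batch normalization (following the original
design); per-level convolution counts and `base_filters` are configurable
since the classic references differ.

## Loss and optimization

The dice coefficient `(2·Σpt + s)/(Σp + Σt + s)` with smoothing `s = 1`
doubles as the loss (`1 − dice`); it is insensitive to the heavy class
imbalance of low-cover tiles.  By default a single dice is computed over the
pooled batch pixels ("batch" aggregation, the common flattened formulation);
a per-tile dice averaged over the batch ("sample") is available when tiles
should contribute gradients scaled to their own canopy area.  The optimizer is RMSprop (ρ = 0.9,
ε = 1e-7); its second-moment cache is warm-started at the first gradient's
square, removing the oversized cold-start updates of the plain recursion.
The reference schedule is 20 epochs × 50 000 steps, batch 16, learning rate
1e-4.

After each epoch, mean per-tile pixel accuracy (threshold 0.5) on the
un-augmented hold-off tiles is computed, and epoch weights are retained only
if that accuracy *strictly exceeds the last retained epoch's* — a dip never
lowers the bar (the literal previous-epoch comparison is available as
`checkpoint_rule="previous_epoch"`).  The returned model carries the best
retained weights.  Non-finite losses abort with the epoch/step index.

### Desk profile

The shipped single-CPU profile keeps the data model and tile geometry but
runs a 4-level U-net (base 16 filters, bottleneck 16 × 16 px) on a schedule
scaled to desk scale: 10 epochs × 40 steps, batch 16 (400 updates instead of
10⁶), with the learning rate raised to 3e-4 to compensate for the ~2 500×
shorter schedule.  Dropping the fifth level costs little for this task — the
texture grain and canopy relief that carry the class signal live well above
the 16-px bottleneck scale — and buys roughly 60% more optimizer updates per
minute, which matters far more at desk scale.  The full 5-level reference
architecture remains the package default and trains the same way, just
slower.  On the default synthetic scene the desk profile trains in roughly
14 minutes on one CPU core.  At this learning rate the loss trajectory
oscillates — an epoch can collapse and recover — and the many short epochs
give the checkpoint rule frequent snapshots from which it retains the best
state, which is exactly the regime that rule was designed for.

## Evaluation

Validation tiles are grouped by reference cover into three strata: [0, ⅓),
[⅓, ⅔), [⅔, 1] ("0–33%", "33–66%", "66–100%"; the boundary values are read
as exact thirds, boundaries half-open, last closed).  Per-stratum accuracy
is the mean *tile-level* pixel accuracy (tiles weigh equally, not pixels);
the summary accuracy is the unweighted mean over occupied strata, so a
background-dominated tile population cannot inflate the headline number.
Empty strata are excluded and reported absent.  Bias is the mean residual
of tile-level predicted cover (mean of thresholded labels) minus reference
cover — positive bias means over-prediction; a per-pixel probability
residual is reported alongside for transparency, as is the tile-weighted
accuracy.

## Map reconstruction

An extract is covered by a regular grid of tile-sized cells; each cell's
predictors are assembled exactly as during training (including per-window
DEM normalization) and predicted; outputs are placed back at their origins.
When the extract edge is not a multiple of 128 px the last row/column of
cells is anchored flush with the far edge and, in the overlap, the later
cell's prediction wins — guaranteeing that every pixel is predicted exactly
once by a full-size tile.  Labels come from one global 0.5 threshold on the
merged probabilities.  Abutting cells can show visible seams; overlapped
inference with averaging is a deliberate non-default extension.

## Reproducibility

Every stochastic element (scene synthesis, tile sampling and splits, weight
initialization, batch selection, augmentation draws) derives from a single
global seed through named `numpy.random.SeedSequence` fan-out.  Identical
configs and seeds give bit-identical scenes, tile sets, training logs and
maps on a fixed platform (floating-point reductions are
implementation-ordered, so cross-platform bit-identity is not claimed).

## Known limitations

* Single binary target class per model; multi-class mapping means one model
  per class.
* Rasters must be co-registered on one grid; no reprojection or resampling.
* Polygon input is GeoJSON (no shapefile reader in the dependency set).
* CPU-only training limits practical schedules to desk scale; the
  implementation is nonetheless faithful to the reference schedule, which is
  a configuration away given more compute.
* The synthetic generator's texture family is stationary Gaussian speckle;
  real canopy texture is non-Gaussian and non-stationary, so transfer of
  accuracy numbers from synthetic scenes to field data is not implied.
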