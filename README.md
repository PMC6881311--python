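# canopyseg

Semantic segmentation of vegetation canopies in very-high-resolution UAV
orthoimagery, for ecologists and remote-sensing practitioners mapping a
target plant species or community (invasive shrubs, plantation trees,
successional communities) from centimetre-scale RGB mosaics and
photogrammetric elevation models.

At ~3 cm ground sampling distance, plant classes are told apart by spatial
*texture* — crown speckle, branch patterning, canopy gaps — rather than by
mean color, which defeats per-pixel classifiers.  `canopyseg` implements the
standard deep-learning answer end to end:

1. **Reference data** — delineated canopy polygons are rasterized to a binary
   mask *y* ∈ {0,1} on the orthomosaic grid (pixel-center rule).
2. **Tiling** — 128 × 128-px tiles of predictors **x** (R, G, B and the DEM
   normalized per tile window to 0–255, all scaled to [0,1]) are sampled on a
   regular grid with 5 m spacing (no overlap), split 66.6 / 33.4 into
   training pool and validation, with 20% of the pool held off for per-epoch
   checkpointing.
3. **Model** — a 5-level U-net: two 3×3 convolutions + ReLU per level, 2×2
   max pooling, feature depths 16·2^(k−1), a decoder of 2×2 up-convolutions
   with skip concatenation, sigmoid output p̂ ∈ [0,1] per pixel.  Forward and
   backward passes are pure NumPy — no GPU or DL framework needed.
4. **Training** — RMSprop on the dice loss
   L = 1 − (2 Σ p̂y + s)/(Σ p̂ + Σ y + s), with joint image/mask augmentation
   (shear 0–0.2 rad, rotations in 20° steps, shifts ≤ 15%, flips); epoch
   weights are kept only when hold-off accuracy strictly improves.
5. **Evaluation** — validation pixel accuracy stratified by target-class
   cover (0–33 / 33–66 / 66–100%) plus the cover bias (mean residual of
   predicted vs reference cover).
6. **Mapping** — the trained net is applied over a scene extract on a regular
   tile grid and merged into one georeferenced probability/label map.

Because UAV campaigns of this kind are rarely redistributable, the package
ships a synthetic-scene generator whose classes differ in texture (and canopy
relief) but *not* in mean color — the statistical regime the method is built
for — including sub-tile canopy sizes, cast shadows and sparse canopies.
See `docs/methods.md` for the full model description and design choices.

## Worked example

```bash
canopyseg run --seed 1 --out runs/demo
```

or equivalently, in Python:

```python
from canopyseg import desk_profile, run_pipeline
run_dir = run_pipeline(desk_profile(seed=1, out_dir="runs/demo"))
```

This generates a 60 m × 60 m scene (2000 × 2000 px at 3 cm GSD, 30 canopies,
~30% cover), samples 144 tiles (77 train / 19 hold-off / 48 validation),
trains the desk-profile U-net (4 levels, 16 base filters, 10 epochs ×
40 steps, batch 16, ~15 min on one CPU core), and writes the evaluation
report and the merged segmentation map.  The training log ends:

```
epoch 9/10: loss 0.1357, hold-off accuracy 0.8011
epoch 10/10: loss 0.4081, hold-off accuracy 0.9380 *
```

(`*` marks epochs retained by the checkpoint rule; the dice/RMSprop
trajectory oscillates at desk scale, which is exactly what the rule absorbs.)
`runs/demo/evaluation.tsv` then reads:

```
metric	value
accuracy_pct	94.8
bias	0.0344
accuracy_cover_0.00_0.33	0.9326	(n=34)
accuracy_cover_0.33_0.67	0.9392	(n=4)
accuracy_cover_0.67_1.00	0.9718	(n=10)
mean_dice	0.7442
```

Reading: per-stratum pixel accuracies are averaged with equal stratum weight
into the headline 94.8% — the model segments low-, mid- and high-cover tiles
alike, so accuracy is not an artifact of background-dominated tiles — and the
small bias (+0.034 cover fraction) shows no strong systematic over- or
under-prediction.  `runs/demo/map/` holds the scene-wide probability and
label GeoTIFFs with the scene's georeferencing (mapped cover 0.331 vs 0.299
reference).  On a separate scene with shadow raised, the false-negative rate
inside shadowed canopy (0.055) exceeds the unshadowed rate (0.012) — very
dark cast shadow is the dominant residual error source, as expected for this
kind of imagery.

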