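"""Regular-grid tile sampling, predictor assembly and train/hold-off/validation splits.

Training tiles are 128x128 pixel windows cut from the orthomosaic on a regular
grid with metric spacing wide enough that no two tiles overlap.  Each tile
stacks four predictor channels — R, G, B and the locally 0-255-normalized DEM,
all conditioned to [0, 1] — together with the rasterized reference mask.  Tiles
are split 66.6/33.3 into a training pool and an independent validation set,
with 20% of the training pool held off for the per-epoch checkpoint metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geodata_io import BinaryMask, RasterGrid, normalize_window, read_raster, write_raster
from .synthetic_scene import Scene

__all__ = ["TileSpec", "Tile", "TileSet", "sample_tiles", "tile_cover", "assemble_predictors"]


@dataclass(frozen=True)
class TileSpec:
    tile_px: int = 128
    grid_spacing_m: float = 5.0
    max_tiles: int = 4000
    train_fraction: float = 0.666
    holdoff_fraction: float = 0.20
    grid_offset_random: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tile_px <= 0:
            raise ValueError("tile_px must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError(f"train_fraction {self.train_fraction} outside (0, 1)")
        if not 0 <= self.holdoff_fraction < 1:
            raise ValueError(f"holdoff_fraction {self.holdoff_fraction} outside [0, 1)")


@dataclass
class Tile:
    """Predictors (4, tile_px, tile_px) in [0,1]; mask (tile_px, tile_px) in {0,1}."""

    predictors: np.ndarray
    mask: np.ndarray
    origin: tuple[int, int]  # (row, col) of the upper-left pixel in the scene

    @property
    def cover(self) -> float:
        return tile_cover(self.mask)


@dataclass
class TileSet:
    train: list[Tile]
    holdoff: list[Tile]
    validation: list[Tile]
    spec: TileSpec
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        origins = [t.origin for part in (self.train, self.holdoff, self.validation) for t in part]
        if len(origins) != len(set(origins)):
            raise ValueError("tile partitions are not disjoint by origin")

    @property
    def n_tiles(self) -> int:
        return len(self.train) + len(self.holdoff) + len(self.validation)

    def all_tiles(self) -> list[Tile]:
        return [*self.train, *self.holdoff, *self.validation]


def tile_cover(mask_tile: np.ndarray) -> float:
    """Target-class cover of a tile: the arithmetic mean of its binary mask."""
    mask_tile = np.asarray(mask_tile)
    bad = np.setdiff1d(np.unique(mask_tile), [0, 1])
    if bad.size:
        raise ValueError(f"mask tile contains non-binary values {bad[:5]}")
    return float(np.asarray(mask_tile, dtype=np.float64).mean())


def assemble_predictors(rgb: np.ndarray, dem: np.ndarray) -> np.ndarray:
    """Stack RGB/255 with the window-normalized DEM/255 into a (4, h, w) array.

    The DEM window is first rescaled to relative 0-255 heights (removing the
    absolute terrain trend within the window) and then conditioned by the same
    1/255 factor as the 8-bit imagery, so all channels are commensurate.
    """
    rgb = np.asarray(rgb, dtype=np.float32)
    if rgb.ndim != 3 or rgb.shape[0] != 3:
        raise ValueError(f"expected (3, h, w) RGB window, got {rgb.shape}")
    dem_rel = normalize_window(np.asarray(dem, dtype=np.float64)).astype(np.float32)
    return np.concatenate([rgb / 255.0, dem_rel[None] / 255.0], axis=0)


def candidate_origins(shape: tuple[int, int], gsd_m: float, spec: TileSpec,
                      rng: np.random.Generator | None = None) -> list[tuple[int, int]]:
    """Pixel origins of a regular grid with metric spacing, fully inside the scene."""
    rows, cols = shape
    tile_m = spec.tile_px * gsd_m
    if spec.grid_spacing_m < tile_m:
        raise ValueError(
            f"grid spacing {spec.grid_spacing_m} m is smaller than the tile edge "
            f"{tile_m} m: sampled tiles would overlap"
        )
    step_px = spec.grid_spacing_m / gsd_m
    off_r = off_c = 0.0
    if spec.grid_offset_random and rng is not None:
        off_r = rng.uniform(0.0, step_px)
        off_c = rng.uniform(0.0, step_px)
    origins = []
    r = off_r
    while int(np.floor(r)) + spec.tile_px <= rows:
        c = off_c
        while int(np.floor(c)) + spec.tile_px <= cols:
            origins.append((int(np.floor(r)), int(np.floor(c))))
            c += step_px
        r += step_px
    return origins


def sample_tiles(scene: Scene, mask: BinaryMask, spec: TileSpec) -> TileSet:
    """Draw up to ``max_tiles`` non-overlapping tiles from a regular grid, split them.

    Grid positions are candidate origins; a seeded uniform subset is taken,
    and each tile is assigned to train / hold-off / validation by a seeded
    random split with the spec's fractions.  The DEM channel is normalized
    within each tile's own window.
    """
    if scene.shape != mask.shape:
        raise ValueError(f"scene {scene.shape} and mask {mask.shape} are not co-registered")
    rng = np.random.default_rng(spec.seed)
    gsd_m = abs(scene.geotransform.a)
    origins = candidate_origins(scene.shape, gsd_m, spec, rng)
    if not origins:
        raise ValueError(
            f"no {spec.tile_px}-px tile fits inside scene of shape {scene.shape} "
            f"with spacing {spec.grid_spacing_m} m"
        )
    order = rng.permutation(len(origins))
    chosen = [origins[i] for i in order[: spec.max_tiles]]

    tiles = []
    rgb = scene.rgb.values
    dem = scene.dem.values
    t = spec.tile_px
    for r0, c0 in chosen:
        predictors = assemble_predictors(rgb[:, r0:r0 + t, c0:c0 + t],
                                         dem[r0:r0 + t, c0:c0 + t])
        tiles.append(Tile(predictors=predictors,
                          mask=mask.values[r0:r0 + t, c0:c0 + t].copy(),
                          origin=(r0, c0)))

    n = len(tiles)
    n_val = int(round((1.0 - spec.train_fraction) * n))
    n_train_pool = n - n_val
    n_holdoff = int(round(spec.holdoff_fraction * n_train_pool))
    perm = rng.permutation(n)
    val_idx = set(perm[:n_val].tolist())
    hold_idx = set(perm[n_val:n_val + n_holdoff].tolist())
    split = {"train": [], "holdoff": [], "validation": []}
    for i, tile in enumerate(tiles):
        if i in val_idx:
            split["validation"].append(tile)
        elif i in hold_idx:
            split["holdoff"].append(tile)
        else:
            split["train"].append(tile)
    return TileSet(
        train=split["train"],
        holdoff=split["holdoff"],
        validation=split["validation"],
        spec=spec,
        provenance={"seed": spec.seed, "n_candidates": len(origins),
                    "scene_shape": scene.shape, "gsd_m": gsd_m},
    )


def write_tileset(tileset: TileSet, out_dir: str | Path, geotransform=None,
                  crs_id: str | None = None) -> Path:
    """Persist tiles as paired GeoTIFFs plus a plain-text manifest."""
    from .geom import GeoTransform

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["tile_id\trow\tcol\tsplit\tcover"]
    idx = 0
    for split_name in ("train", "holdoff", "validation"):
        for tile in getattr(tileset, split_name):
            r0, c0 = tile.origin
            gt = (geotransform.window(r0, c0) if geotransform is not None
                  else GeoTransform.north_up(0.0, 0.0, 1.0))
            write_raster(out / f"tile_{idx:05d}_pred.tif",
                         RasterGrid(tile.predictors.astype(np.float32), gt, crs_id))
            write_raster(out / f"tile_{idx:05d}_mask.tif",
                         RasterGrid(tile.mask.astype(np.uint8), gt, crs_id))
            lines.append(f"{idx:05d}\t{r0}\t{c0}\t{split_name}\t{tile.cover:.6f}")
            idx += 1
    (out / "manifest.tsv").write_text("\n".join(lines) + "\n")
    return out


def read_tileset(in_dir: str | Path, spec: TileSpec | None = None) -> TileSet:
    """Load a tile directory written by :func:`write_tileset`."""
    in_dir = Path(in_dir)
    manifest = (in_dir / "manifest.tsv").read_text().strip().splitlines()[1:]
    split: dict[str, list[Tile]] = {"train": [], "holdoff": [], "validation": []}
    for line in manifest:
        tile_id, row, col, split_name, _cover = line.split("\t")
        pred = read_raster(in_dir / f"tile_{tile_id}_pred.tif").values
        mask = read_raster(in_dir / f"tile_{tile_id}_mask.tif").values
        split[split_name].append(Tile(predictors=pred, mask=mask,
                                      origin=(int(row), int(col))))
    return TileSet(train=split["train"], holdoff=split["holdoff"],
                   validation=split["validation"], spec=spec or TileSpec(),
                   provenance={"source": str(in_dir)})
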