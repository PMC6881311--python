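"""Scene-scale inference: tile an extract on a regular grid, merge predictions
into one georeferenced segmentation map.

An extract (e.g. 120 x 120 m at 3 cm GSD = 4000 x 4000 pixels) is covered by a
regular grid of tile-sized cells; each cell's predictors are assembled exactly
as during training (including per-tile DEM normalization), predicted, and the
tile outputs are placed back at their origins.  When the extract edge is not a
multiple of the tile size, the last row/column of cells is anchored flush to
the far edge; in the resulting overlap, the later cell's prediction wins.
Labels are derived from the merged probabilities by one global threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geodata_io import RasterGrid, write_raster
from .geom import GeoTransform
from .synthetic_scene import Scene
from .tiling import assemble_predictors
from .unet_model import UNet

__all__ = ["SegmentationMap", "map_extract", "grid_cells"]


@dataclass
class SegmentationMap:
    probabilities: np.ndarray  # (rows, cols) in [0, 1]
    labels: np.ndarray         # (rows, cols) in {0, 1}
    geotransform: GeoTransform
    crs_id: str | None
    extent_m: tuple[float, float]

    @property
    def shape(self) -> tuple[int, int]:
        return self.probabilities.shape

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_raster(out / "probability.tif",
                     RasterGrid(self.probabilities.astype(np.float32),
                                self.geotransform, self.crs_id))
        write_raster(out / "labels.tif",
                     RasterGrid(self.labels.astype(np.uint8),
                                self.geotransform, self.crs_id))
        return out


def grid_cells(rows: int, cols: int, tile_px: int) -> list[tuple[int, int]]:
    """Origins of a regular cell grid covering an extract, last cells edge-flush."""
    if rows < tile_px or cols < tile_px:
        raise ValueError(f"extract {rows}x{cols} smaller than one {tile_px}-px tile")

    def axis(n: int) -> list[int]:
        starts = list(range(0, n - tile_px + 1, tile_px))
        if starts[-1] + tile_px < n:
            starts.append(n - tile_px)
        return starts

    return [(r, c) for r in axis(rows) for c in axis(cols)]


def map_extract(scene: Scene, model: UNet,
                extract_window: tuple[float, float, float, float] | None = None,
                tile_px: int = 128, threshold: float = 0.5,
                batch: int = 8) -> SegmentationMap:
    """Segment a rectangular extract of a scene with a trained model.

    ``extract_window`` is a map-coordinate rectangle ``(x0, y0, x1, y1)``;
    None maps the whole scene.  Every extract pixel receives exactly one
    prediction and the output inherits the extract's georeferencing.
    """
    rows, cols = scene.shape
    gt = scene.geotransform
    if extract_window is None:
        r0, c0, r1, c1 = 0, 0, rows, cols
    else:
        x0, y0, x1, y1 = extract_window
        rr, cc = gt.map_to_pixel([x0, x1], [y0, y1])
        r0, r1 = int(round(rr.min())), int(round(rr.max()))
        c0, c1 = int(round(cc.min())), int(round(cc.max()))
        if r0 < 0 or c0 < 0 or r1 > rows or c1 > cols:
            raise ValueError(f"extract window {extract_window} outside scene bounds")
    ext_rows, ext_cols = r1 - r0, c1 - c0
    cells = grid_cells(ext_rows, ext_cols, tile_px)

    rgb = scene.rgb.values
    dem = scene.dem.values
    probs = np.zeros((ext_rows, ext_cols), dtype=np.float64)
    for i in range(0, len(cells), batch):
        chunk = cells[i:i + batch]
        x = np.stack([
            np.moveaxis(assemble_predictors(
                rgb[:, r0 + cr:r0 + cr + tile_px, c0 + cc:c0 + cc + tile_px],
                dem[r0 + cr:r0 + cr + tile_px, c0 + cc:c0 + cc + tile_px]), 0, -1)
            for cr, cc in chunk
        ]).astype(np.float32)
        out = model.predict(x)
        for j, (cr, cc) in enumerate(chunk):
            probs[cr:cr + tile_px, cc:cc + tile_px] = out[j]

    gsd = abs(gt.a)
    return SegmentationMap(
        probabilities=probs,
        labels=(probs >= threshold).astype(np.uint8),
        geotransform=gt.window(r0, c0),
        crs_id=scene.crs_id,
        extent_m=(ext_cols * gsd, ext_rows * gsd),
    )
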