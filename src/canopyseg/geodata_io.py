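"""Raster/vector I/O, polygon rasterization and DEM normalization.

Rasters are stored as GeoTIFF with ModelPixelScale/ModelTiepoint/GeoKeyDirectory
tags; vector reference data as GeoJSON in the raster CRS.  Reference polygons
are burned to binary masks by the pixel-*center* containment rule, and DEM
windows are rescaled to relative 0-255 heights to remove terrain trend before
they enter the predictor stack.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
import tifffile
from shapely.geometry import mapping as geom_mapping, shape as geom_shape

from .geom import GeoTransform

logger = logging.getLogger(__name__)

__all__ = [
    "RasterGrid",
    "BinaryMask",
    "read_raster",
    "write_raster",
    "rasterize_polygons",
    "normalize_dem",
    "normalize_window",
    "read_polygons",
    "write_polygons",
]

_ALLOWED_BANDS = (1, 3, 4)

# GeoTIFF tag ids
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735


@dataclass
class RasterGrid:
    """A georeferenced raster: 2-D ``(rows, cols)`` or 3-D ``(bands, rows, cols)``."""

    values: np.ndarray
    geotransform: GeoTransform
    crs_id: str | None = None
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim not in (2, 3):
            raise ValueError(f"raster must be 2-D or 3-D, got ndim={self.values.ndim}")
        if self.n_bands not in _ALLOWED_BANDS:
            raise ValueError(
                f"band count {self.n_bands} unsupported (expected one of {_ALLOWED_BANDS})"
            )
        if min(self.shape) <= 0:
            raise ValueError(f"raster has empty dimensions {self.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[-2], self.values.shape[-1]

    @property
    def n_bands(self) -> int:
        return 1 if self.values.ndim == 2 else self.values.shape[0]


@dataclass
class BinaryMask:
    """A {0,1} label raster sharing a raster grid's georeferencing."""

    values: np.ndarray
    geotransform: GeoTransform
    crs_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")
        bad = np.setdiff1d(np.unique(self.values), [0, 1])
        if bad.size:
            raise ValueError(f"mask contains non-binary values {bad[:5]}")
        self.values = self.values.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _epsg_code(crs_id: str | None) -> int | None:
    if crs_id is None:
        return None
    text = str(crs_id).upper().replace("EPSG:", "").strip()
    try:
        return int(text)
    except ValueError:
        return None


def _geo_extratags(gt: GeoTransform, crs_id: str | None):
    if gt.b != 0.0 or gt.d != 0.0:
        raise ValueError("GeoTIFF export supports axis-aligned geotransforms only")
    tags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (abs(gt.a), abs(gt.e), 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, gt.c, gt.f, 0.0)),
    ]
    epsg = _epsg_code(crs_id)
    if epsg is not None:
        # minimal projected-CRS geokey directory: model type, raster type, EPSG code
        keys = (1, 1, 0, 3, 1024, 0, 1, 1, 1025, 0, 1, 1, 3072, 0, 1, epsg)
        tags.append((_GEO_KEY_DIRECTORY, "H", len(keys), keys))
    return tags


def write_raster(path: str | Path, grid: RasterGrid) -> Path:
    """Write a grid as a GeoTIFF; 3-band uint8 rasters are tagged as RGB."""
    path = Path(path)
    values = grid.values
    if values.ndim == 3:
        data = np.moveaxis(values, 0, -1)  # pixel-interleaved
    else:
        data = values
    if grid.n_bands == 3 and values.dtype == np.uint8:
        photometric = "rgb"
    else:
        photometric = "minisblack"
    tifffile.imwrite(
        path,
        data,
        photometric=photometric,
        planarconfig="contig" if values.ndim == 3 else None,
        extratags=_geo_extratags(grid.geotransform, grid.crs_id),
    )
    return path


def read_raster(path: str | Path) -> RasterGrid:
    """Read a GeoTIFF into a RasterGrid, band order preserved.

    A raster with no CRS geokeys is read with ``crs_id=None`` and a warning;
    unreadable files raise ``IOError`` naming the path.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"raster file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = page.asarray()
            tags = page.tags
            scale = tags[_MODEL_PIXEL_SCALE].value if _MODEL_PIXEL_SCALE in tags else None
            tiepoint = tags[_MODEL_TIEPOINT].value if _MODEL_TIEPOINT in tags else None
            geokeys = tags[_GEO_KEY_DIRECTORY].value if _GEO_KEY_DIRECTORY in tags else None
    except (tifffile.TiffFileError, ValueError) as exc:
        raise IOError(f"cannot read raster {path}: {exc}") from exc

    if scale is None or tiepoint is None:
        raise IOError(f"raster {path} lacks georeferencing tags")
    gt = GeoTransform(float(scale[0]), 0.0, float(tiepoint[3]),
                      0.0, -float(scale[1]), float(tiepoint[4]))

    crs_id = None
    if geokeys is not None:
        keys = np.asarray(geokeys).reshape(-1, 4)
        for key_id, _, _, value in keys[1:]:
            if key_id == 3072:
                crs_id = f"EPSG:{int(value)}"
    if crs_id is None:
        warnings.warn(f"raster {path} has no CRS; recording CRS as unknown", stacklevel=2)

    if data.ndim == 3:
        data = np.moveaxis(data, -1, 0)
    return RasterGrid(values=data, geotransform=gt, crs_id=crs_id)


def rasterize_polygons(polygons, template: RasterGrid | BinaryMask) -> BinaryMask:
    """Burn polygons to a binary mask: pixel=1 iff its center lies inside any polygon.

    Overlapping polygons rasterize to their union.  An empty collection yields
    an all-zero mask.  Invalid geometries are rejected with their index.
    """
    rows, cols = template.shape
    gt = template.geotransform
    mask = np.zeros((rows, cols), dtype=np.uint8)
    for idx, poly in enumerate(polygons):
        if poly.is_empty:
            continue
        if not poly.is_valid:
            raise ValueError(f"polygon {idx} is invalid (self-intersecting or degenerate)")
        # restrict the point-in-polygon test to the polygon's pixel bounding box
        minx, miny, maxx, maxy = poly.bounds
        corners_r, corners_c = gt.map_to_pixel([minx, maxx, minx, maxx], [miny, miny, maxy, maxy])
        r0 = max(int(np.floor(corners_r.min())) - 1, 0)
        r1 = min(int(np.ceil(corners_r.max())) + 1, rows)
        c0 = max(int(np.floor(corners_c.min())) - 1, 0)
        c1 = min(int(np.ceil(corners_c.max())) + 1, cols)
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        x, y = gt.pixel_center_to_map(rr.ravel(), cc.ravel())
        inside = shapely.contains_xy(poly, x, y).reshape(rr.shape)
        mask[r0:r1, c0:c1] |= inside.astype(np.uint8)
    return BinaryMask(values=mask, geotransform=gt, crs_id=template.crs_id)


def normalize_window(values: np.ndarray) -> np.ndarray:
    """Rescale heights linearly to 0-255; a constant window maps to all zeros."""
    values = np.asarray(values, dtype=np.float64)
    lo = values.min()
    hi = values.max()
    if hi == lo:
        logger.warning("constant DEM window (value %.3f): normalized to zeros", lo)
        return np.zeros_like(values)
    return (values - lo) / (hi - lo) * 255.0


def normalize_dem(dem: RasterGrid, window: tuple[int, int, int, int] | None = None) -> RasterGrid:
    """Normalize absolute DEM heights to relative 0-255 values within a window.

    ``window`` is half-open pixel bounds ``(row0, row1, col0, col1)``; None
    normalizes the whole raster.  Removing the absolute height trend locally is
    what lets a model use canopy *relief* rather than terrain elevation.
    """
    if dem.n_bands != 1:
        raise ValueError(f"DEM must be single-band, got {dem.n_bands} bands")
    rows, cols = dem.shape
    if window is None:
        window = (0, rows, 0, cols)
    r0, r1, c0, c1 = window
    if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
        raise ValueError(f"window {window} outside DEM bounds {(rows, cols)}")
    sub = dem.values[r0:r1, c0:c1]
    out = normalize_window(sub)
    return RasterGrid(
        values=out,
        geotransform=dem.geotransform.window(r0, c0),
        crs_id=dem.crs_id,
        nodata=None,
    )


def write_polygons(path: str | Path, polygons, crs_id: str | None = None) -> Path:
    """Write polygons as a GeoJSON FeatureCollection (coordinates in the raster CRS)."""
    path = Path(path)
    features = [
        {"type": "Feature", "properties": {"id": i}, "geometry": geom_mapping(p)}
        for i, p in enumerate(polygons)
    ]
    doc = {"type": "FeatureCollection", "features": features}
    if crs_id is not None:
        doc["crs"] = {"type": "name", "properties": {"name": str(crs_id)}}
    path.write_text(json.dumps(doc))
    return path


def read_polygons(path: str | Path):
    """Read a GeoJSON FeatureCollection; returns (list of shapely polygons, crs_id)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"vector file not found: {path}")
    doc = json.loads(path.read_text())
    polygons = [geom_shape(feat["geometry"]) for feat in doc.get("features", [])]
    crs_id = doc.get("crs", {}).get("properties", {}).get("name")
    return polygons, crs_id
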