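"""Affine pixel-to-map georeferencing.

A :class:`GeoTransform` maps pixel coordinates to map coordinates the way
GDAL-style geotransforms do: ``x = a*col + b*row + c`` and
``y = d*col + e*row + f``, with ``(c, f)`` the map position of the upper-left
corner of pixel (0, 0).  Pixel coordinates are row-major and 0-based; pixel
*centers* sit at half-integer offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GeoTransform"]


@dataclass(frozen=True)
class GeoTransform:
    a: float  # column pixel size (map units per column step)
    b: float  # row rotation term
    c: float  # x of the upper-left corner of pixel (0, 0)
    d: float  # column rotation term
    e: float  # row pixel size (negative for north-up rasters)
    f: float  # y of the upper-left corner of pixel (0, 0)

    @classmethod
    def north_up(cls, x0: float, y0: float, pixel_size: float) -> "GeoTransform":
        """Square-pixel, axis-aligned transform with origin at the top-left."""
        return cls(pixel_size, 0.0, x0, 0.0, -pixel_size, y0)

    @property
    def determinant(self) -> float:
        return self.a * self.e - self.b * self.d

    def __post_init__(self) -> None:
        if abs(self.determinant) < 1e-15:
            raise ValueError("geotransform is singular (zero pixel area)")

    def pixel_to_map(self, row, col):
        """Map coordinates of the upper-left corner of pixel (row, col)."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = self.a * col + self.b * row + self.c
        y = self.d * col + self.e * row + self.f
        return x, y

    def pixel_center_to_map(self, row, col):
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        return self.pixel_to_map(row + 0.5, col + 0.5)

    def map_to_pixel(self, x, y):
        """Fractional (row, col) of a map coordinate."""
        x = np.asarray(x, dtype=float) - self.c
        y = np.asarray(y, dtype=float) - self.f
        det = self.determinant
        col = (self.e * x - self.b * y) / det
        row = (self.a * y - self.d * x) / det
        return row, col

    def window(self, row0: int, col0: int) -> "GeoTransform":
        """Transform of a sub-raster whose pixel (0, 0) is (row0, col0) here."""
        x, y = self.pixel_to_map(row0, col0)
        return GeoTransform(self.a, self.b, float(x), self.d, self.e, float(y))

    def to_tuple(self):
        return (self.a, self.b, self.c, self.d, self.e, self.f)
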