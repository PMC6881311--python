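import numpy as np
import pytest
from matplotlib.path import Path as MplPath
from shapely.geometry import Polygon, box

from canopyseg.geodata_io import (
    BinaryMask,
    RasterGrid,
    normalize_dem,
    normalize_window,
    rasterize_polygons,
    read_polygons,
    read_raster,
    write_polygons,
    write_raster,
)
from canopyseg.geom import GeoTransform


def _grid(values, gsd=1.0, x0=0.0, y0=None, crs="EPSG:32719"):
    rows = values.shape[-2]
    if y0 is None:
        y0 = rows * gsd
    return RasterGrid(values, GeoTransform.north_up(x0, y0, gsd), crs)


class TestRasterRoundTrip:
    @pytest.mark.parametrize("values", [
        (np.arange(12, dtype=np.uint8).reshape(3, 2, 2)),
        (np.linspace(0.0, 7.5, 16, dtype=np.float32).reshape(4, 4)),
        ((np.arange(64, dtype=np.uint8).reshape(4, 4, 4))),
    ], ids=["rgb-uint8", "dem-float32", "four-band"])
    def test_write_read_preserves_values_and_georef(self, tmp_path, values):
        grid = _grid(values, gsd=0.03)
        path = write_raster(tmp_path / "r.tif", grid)
        back = read_raster(path)
        np.testing.assert_array_equal(back.values, grid.values)
        assert back.geotransform == grid.geotransform
        assert back.crs_id == grid.crs_id

    def test_single_band_dem_has_band_count_one(self, tmp_path):
        grid = _grid(np.ones((5, 6), dtype=np.float32))
        back = read_raster(write_raster(tmp_path / "d.tif", grid))
        assert back.n_bands == 1

    def test_missing_file_raises_ioerror_naming_path(self, tmp_path):
        with pytest.raises(IOError, match="nope.tif"):
            read_raster(tmp_path / "nope.tif")

    def test_non_raster_file_raises_ioerror(self, tmp_path):
        bad = tmp_path / "bad.tif"
        bad.write_text("this is not a tiff")
        with pytest.raises(IOError):
            read_raster(bad)

    def test_missing_crs_warns_and_reads_unknown(self, tmp_path):
        grid = _grid(np.ones((4, 4), dtype=np.uint8), crs=None)
        path = write_raster(tmp_path / "nocrs.tif", grid)
        with pytest.warns(UserWarning, match="no CRS"):
            back = read_raster(path)
        assert back.crs_id is None


class TestRasterizePolygons:
    def test_empty_layer_gives_all_zero_mask(self):
        template = _grid(np.zeros((100, 100), dtype=np.uint8))
        mask = rasterize_polygons([], template)
        assert mask.values.sum() == 0
        assert mask.values.shape == (100, 100)

    def test_exact_rectangle_covers_expected_pixels(self):
        # rows 10-19, cols 10-19 of a unit-pixel north-up grid:
        # x in [10, 20), y in [80, 90) for a 100-row raster
        template = _grid(np.zeros((100, 100), dtype=np.uint8))
        rect = box(10.0, 80.0, 20.0, 90.0)
        mask = rasterize_polygons([rect], template)
        assert mask.values.sum() == 100
        rr, cc = np.nonzero(mask.values)
        assert rr.min() == 10 and rr.max() == 19
        assert cc.min() == 10 and cc.max() == 19

    def test_overlapping_polygons_equal_union(self):
        template = _grid(np.zeros((60, 60), dtype=np.uint8))
        a = box(5, 5, 30, 30)
        b = box(20, 20, 50, 50)
        both = rasterize_polygons([a, b], template)
        union = rasterize_polygons([a.union(b)], template)
        np.testing.assert_array_equal(both.values, union.values)

    def test_invalid_polygon_rejected_with_index(self):
        template = _grid(np.zeros((10, 10), dtype=np.uint8))
        bowtie = Polygon([(0, 0), (4, 4), (4, 0), (0, 4)])
        with pytest.raises(ValueError, match="polygon 1"):
            rasterize_polygons([box(1, 1, 2, 2), bowtie], template)

    def test_matches_pixel_center_point_in_polygon_oracle(self, rng):
        """Pixel-for-pixel agreement with brute-force pixel-center containment."""
        template = _grid(np.zeros((64, 64), dtype=np.uint8))
        gt = template.geotransform
        rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        cx, cy = gt.pixel_center_to_map(rr.ravel(), cc.ravel())
        centers = np.column_stack([cx, cy])
        for _ in range(25):
            n_vert = int(rng.integers(3, 9))
            angles = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
            radius = rng.uniform(3, 25, n_vert)
            x0, y0 = rng.uniform(10, 54, 2)
            verts = np.column_stack([x0 + radius * np.cos(angles),
                                     y0 + radius * np.sin(angles)])
            poly = Polygon(verts)
            if not poly.is_valid or poly.area == 0:
                continue
            expected = MplPath(verts).contains_points(centers).reshape(64, 64)
            got = rasterize_polygons([poly], template).values.astype(bool)
            np.testing.assert_array_equal(got, expected)

    def test_area_consistency_bound(self, rng):
        """|pixel count * pixel area - polygon area| <= perimeter * pixel size."""
        template = _grid(np.zeros((128, 128), dtype=np.uint8))
        for _ in range(20):
            n_vert = int(rng.integers(3, 8))
            angles = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
            radius = rng.uniform(5, 40, n_vert)
            x0, y0 = rng.uniform(45, 85, 2)
            poly = Polygon(np.column_stack([x0 + radius * np.cos(angles),
                                            y0 + radius * np.sin(angles)]))
            if not poly.is_valid or poly.area == 0:
                continue
            count = int(rasterize_polygons([poly], template).values.sum())
            assert abs(count * 1.0 - poly.area) <= poly.length * 1.0


class TestNormalizeDem:
    def test_linear_map_endpoints_and_midpoint(self):
        out = normalize_window(np.array([10.0, 20.0, 30.0]))
        np.testing.assert_allclose(out, [0.0, 127.5, 255.0])

    def test_hand_computed_uneven_values(self):
        out = normalize_window(np.array([2.0, 4.0, 8.0]))
        np.testing.assert_allclose(out, [0.0, 85.0, 255.0])

    def test_constant_window_maps_to_zeros(self):
        out = normalize_window(np.array([5.0, 5.0]))
        np.testing.assert_array_equal(out, [0.0, 0.0])

    def test_output_always_within_range(self, rng):
        for _ in range(50):
            vals = rng.normal(100, 30, size=(12, 12))
            out = normalize_window(vals)
            assert out.min() >= 0.0 and out.max() <= 255.0

    def test_windowed_normalization_uses_window_extrema(self):
        dem = _grid(np.arange(100, dtype=np.float32).reshape(10, 10))
        out = normalize_dem(dem, window=(2, 4, 0, 10))
        assert out.values.min() == 0.0 and out.values.max() == 255.0
        assert out.values.shape == (2, 10)

    def test_multiband_rejected(self):
        grid = _grid(np.zeros((3, 5, 5), dtype=np.uint8))
        with pytest.raises(ValueError, match="single-band"):
            normalize_dem(grid)


class TestPolygonIO:
    def test_geojson_round_trip(self, tmp_path):
        polys = [box(0, 0, 5, 5), box(10, 10, 12, 15)]
        path = write_polygons(tmp_path / "p.geojson", polys, crs_id="EPSG:32719")
        back, crs = read_polygons(path)
        assert crs == "EPSG:32719"
        assert len(back) == 2
        for a, b in zip(polys, back):
            assert a.equals(b)


class TestBinaryMask:
    def test_rejects_non_binary_values(self):
        with pytest.raises(ValueError, match="non-binary"):
            BinaryMask(np.array([[0, 2]]), GeoTransform.north_up(0, 1, 1.0))
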