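import numpy as np
import pytest
from scipy import ndimage

from canopyseg.synthetic_scene import SceneConfig, generate_scene, scene_cover_fraction
from conftest import small_scene_config


class TestSceneGeometry:
    def test_pixel_grid_follows_extent_and_gsd(self):
        cfg = small_scene_config(width_m=30.0, height_m=30.0, gsd_m=0.03,
                                 n_canopies=2, canopy_radius_range_m=(1.0, 2.0))
        scene = generate_scene(cfg)
        assert scene.shape == (1000, 1000)
        assert scene.rgb.values.shape == (3, 1000, 1000)
        assert scene.dem.values.shape == (1000, 1000)

    def test_non_integer_extent_rejected_naming_dimension(self):
        with pytest.raises(ValueError, match="width_m"):
            generate_scene(small_scene_config(width_m=24.01))

    def test_oversized_canopy_rejected(self):
        with pytest.raises(ValueError, match="half the scene extent"):
            generate_scene(small_scene_config(canopy_radius_range_m=(13.0, 14.0)))

    def test_mismatched_mean_colors_rejected(self):
        with pytest.raises(ValueError, match="mean color"):
            generate_scene(small_scene_config(
                mean_color_target=(120.0, 95.0, 72.0)))

    def test_no_canopies_gives_empty_polygons_and_zero_cover(self):
        scene = generate_scene(small_scene_config(n_canopies=0))
        assert scene.polygons == []
        assert scene_cover_fraction(scene) == 0.0

    def test_polygons_lie_inside_scene_extent(self, small_scene):
        for poly in small_scene.polygons:
            minx, miny, maxx, maxy = poly.bounds
            assert minx >= 0 and miny >= 0
            assert maxx <= 24.0 and maxy <= 24.0
            assert poly.is_valid and poly.area > 0

    def test_determinism_bit_identical(self):
        cfg = small_scene_config(seed=7)
        a = generate_scene(cfg)
        b = generate_scene(small_scene_config(seed=7))
        np.testing.assert_array_equal(a.rgb.values, b.rgb.values)
        np.testing.assert_array_equal(a.dem.values, b.dem.values)
        assert len(a.polygons) == len(b.polygons)
        for pa, pb in zip(a.polygons, b.polygons):
            assert pa.equals_exact(pb, 0.0)

    def test_different_seeds_differ(self):
        a = generate_scene(small_scene_config(seed=1))
        b = generate_scene(small_scene_config(seed=2))
        assert not np.array_equal(a.rgb.values, b.rgb.values)


class TestCoverFraction:
    def test_single_square_cover_fraction(self):
        from shapely.geometry import box

        # 10 m x 10 m square in a 100 m x 100 m scene at 1 m GSD -> ~1% cover
        scene = generate_scene(SceneConfig(
            width_m=100.0, height_m=100.0, gsd_m=1.0, n_canopies=0,
            canopy_radius_range_m=(1.0, 2.0), seed=0))
        scene.polygons.append(box(40.0, 40.0, 50.0, 50.0))
        frac = scene_cover_fraction(scene)
        # one boundary-pixel tolerance on a 10x10-px square
        assert frac == pytest.approx(0.01, abs=40 / 10000)


@pytest.fixture(scope="module")
def shadowless_scene():
    # shadows off isolates the texture claim (shadowed pixels are darker
    # by construction and would hand a color classifier free signal)
    return generate_scene(small_scene_config(seed=9, shadow_fraction=0.0))


class TestTextureSignal:
    """The class signal must live in texture, not in mean color."""

    @staticmethod
    def _balanced_subsample(mask, rng, n=4000):
        pos = np.column_stack(np.nonzero(mask))
        neg = np.column_stack(np.nonzero(~mask))
        pos = pos[rng.choice(len(pos), n // 2, replace=False)]
        neg = neg[rng.choice(len(neg), n // 2, replace=False)]
        return pos, neg

    def test_rgb_linear_classifier_near_chance(self, shadowless_scene, rng):
        from sklearn.linear_model import LogisticRegression

        mask = shadowless_scene.reference_mask().values.astype(bool)
        pos, neg = self._balanced_subsample(mask, rng)
        coords = np.vstack([pos, neg])
        X = shadowless_scene.rgb.values[:, coords[:, 0], coords[:, 1]].T.astype(float)
        y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
        clf = LogisticRegression(max_iter=200).fit(X[::2], y[::2])
        acc = clf.score(X[1::2], y[1::2])
        assert acc < 0.60, f"per-pixel RGB classifier should be near chance, got {acc:.3f}"

    @staticmethod
    def _fine_scale_variance(scene, window=9):
        """Local variance at the background speckle scale: high over the
        fine-grained ground texture, low inside the smoother-grained canopy."""
        gray = scene.rgb.values.mean(axis=0)
        local_mean = ndimage.uniform_filter(gray, size=window)
        return ndimage.uniform_filter((gray - local_mean) ** 2, size=window)

    def test_local_variance_separates_classes(self, shadowless_scene):
        local_var = self._fine_scale_variance(shadowless_scene)
        mask = shadowless_scene.reference_mask().values.astype(bool)
        # erode so the statistic is evaluated away from class borders
        interior = ndimage.binary_erosion(mask, iterations=10)
        exterior = ndimage.binary_erosion(~mask, iterations=10)
        pos = local_var[interior]
        neg = local_var[exterior]
        thresh = (np.median(pos) + np.median(neg)) / 2
        balanced_acc = 0.5 * ((pos < thresh).mean() + (neg >= thresh).mean())
        assert balanced_acc > 0.85, f"texture statistic should separate, got {balanced_acc:.3f}"

    def test_polygon_pixels_carry_target_texture(self, shadowless_scene):
        """>=95% of rasterized interior canopy pixels show target-texture statistics."""
        local_var = self._fine_scale_variance(shadowless_scene)
        mask = shadowless_scene.reference_mask().values.astype(bool)
        interior = ndimage.binary_erosion(mask, iterations=10)
        exterior = ndimage.binary_erosion(~mask, iterations=10)
        thresh = (np.median(local_var[interior]) + np.median(local_var[exterior])) / 2
        frac = (local_var[interior] < thresh).mean()
        assert frac >= 0.95


class TestShadowRendering:
    def test_shadow_darkens_both_canopy_border_and_adjacent_ground(self):
        """Cast shadow has two parts: a self-shadowed crescent inside the canopy
        and the silhouette projected onto the down-sun ground, so darkness alone
        does not identify the class."""
        scene = generate_scene(small_scene_config(seed=3, shadow_fraction=0.3))
        mask = scene.reference_mask().values.astype(bool)
        shadow = scene.shadow_mask
        assert (shadow & mask).any() and (shadow & ~mask).any()
        lit = scene.rgb.values[:, mask & ~shadow].mean()
        dark = scene.rgb.values[:, shadow].mean()
        assert dark < 0.6 * lit

    def test_within_canopy_crescent_tracks_requested_fraction(self):
        # occluders off isolates the self-shadow crescents
        scene = generate_scene(small_scene_config(seed=3, shadow_fraction=0.3,
                                                  shadow_occluders=0))
        mask = scene.reference_mask().values.astype(bool)
        frac = (scene.shadow_mask & mask).sum() / mask.sum()
        assert 0.15 < frac < 0.45

    def test_zero_fraction_disables_shadow(self):
        scene = generate_scene(small_scene_config(seed=3, shadow_fraction=0.0))
        assert not scene.shadow_mask.any()


class TestSceneSerialization:
    def test_write_then_read_round_trips(self, small_scene, tmp_path):
        from canopyseg.geodata_io import read_polygons, read_raster

        small_scene.write(tmp_path / "scene")
        rgb = read_raster(tmp_path / "scene" / "ortho_rgb.tif")
        dem = read_raster(tmp_path / "scene" / "dem.tif")
        polys, crs = read_polygons(tmp_path / "scene" / "reference_polygons.geojson")
        np.testing.assert_array_equal(rgb.values, small_scene.rgb.values)
        np.testing.assert_array_equal(dem.values, small_scene.dem.values)
        assert len(polys) == len(small_scene.polygons)
        assert crs == small_scene.crs_id
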