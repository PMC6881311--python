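"""Synthetic UAV-like scenes for testing the canopy-segmentation pipeline.

Real very-high-resolution orthomosaics separate plant canopies from their
surroundings mostly by spatial *texture* (crown speckle, branch patterning)
rather than by mean color, and photogrammetric DEMs add canopy-height relief
on top of sloping terrain.  The generator reproduces exactly those statistics:

* background and target classes share (near-)identical mean RGB, so a
  pixel-wise color classifier is near chance;
* the target class differs in texture grain length, contrast and anisotropy;
* canopies are irregular star-convex blobs with sizes down to below tile
  scale, optionally rendered sparse (target texture interleaved with ground);
* cast shadow darkens a self-shadow crescent on the down-sun canopy border,
  the canopy silhouette projected onto adjacent ground, and elongated patches
  thrown by taller off-class vegetation, so darkness lands on both classes —
  the regime in which dark shadow causes the false negatives reported for
  real flights;
* the DEM is smooth sloping terrain plus tapered canopy-height bumps with
  surface noise, and photogrammetric relief degrades inside shadow, so height
  is informative but not a clean label.

Scenes carry a metric projected CRS placeholder and a north-up geotransform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon

from .geodata_io import BinaryMask, RasterGrid, rasterize_polygons, write_polygons, write_raster
from .geom import GeoTransform

logger = logging.getLogger(__name__)

__all__ = ["TextureParams", "SceneConfig", "Scene", "generate_scene", "scene_cover_fraction"]

_DEFAULT_CRS = "EPSG:32719"  # placeholder metric UTM zone


@dataclass(frozen=True)
class TextureParams:
    """Band-limited speckle descriptor for one class.

    grain_px: correlation length of the speckle in pixels (sets the spatial
    scale of local variance); contrast: standard deviation of the texture in
    8-bit digital numbers; anisotropy_deg: orientation of grain elongation;
    anisotropy_ratio: major/minor grain-length ratio (1 = isotropic).
    """

    grain_px: float
    contrast: float
    anisotropy_deg: float = 0.0
    anisotropy_ratio: float = 1.0


@dataclass
class SceneConfig:
    width_m: float = 60.0
    height_m: float = 60.0
    gsd_m: float = 0.03
    n_canopies: int = 30
    canopy_radius_range_m: tuple[float, float] = (1.5, 6.0)
    texture_target: TextureParams = field(
        default_factory=lambda: TextureParams(grain_px=7.0, contrast=26.0,
                                              anisotropy_deg=30.0, anisotropy_ratio=2.0)
    )
    texture_background: TextureParams = field(
        default_factory=lambda: TextureParams(grain_px=1.5, contrast=18.0)
    )
    shadow_fraction: float = 0.15
    shadow_darkness: float = 0.25  # RGB multiplier inside shadowed pixels
    shadow_azimuth_deg: float = 135.0
    shadow_length_m: float = 2.0  # down-sun reach of the ground-cast shadow
    # (~canopy height over tan(sun elevation); most cast shadow lands on ground)
    # photogrammetric height reconstruction fails in deep shadow: the fraction
    # of canopy relief lost there, plus extra surface noise (metres)
    shadow_dem_attenuation: float = 0.7
    shadow_dem_noise_m: float = 0.3
    # shadows cast into the scene by taller off-class vegetation: elongated
    # patches aligned with the sun azimuth, landing on canopy and ground alike
    shadow_occluders: int = 8
    shadow_occluder_size_m: tuple[float, float] = (2.0, 6.0)
    sparse_fraction: float = 0.0
    sparse_cover: float = 0.45  # within-polygon target-texture cover of sparse canopies
    mean_color_target: tuple[float, float, float] = (82.0, 97.0, 74.0)
    mean_color_background: tuple[float, float, float] = (80.0, 95.0, 72.0)
    mean_color_tolerance: float = 6.0
    terrain_relief_m: float = 3.0
    terrain_slope_m: float = 4.0  # corner-to-corner planar height change
    canopy_height_m: float = 1.8
    dem_noise_m: float = 0.35  # photogrammetric surface noise over canopies
    seed: int = 0

    def validate(self) -> None:
        for name, extent in (("width_m", self.width_m), ("height_m", self.height_m)):
            n = extent / self.gsd_m
            if abs(n - round(n)) > 1e-9 or n <= 0:
                raise ValueError(
                    f"{name}={extent} is not an integer multiple of gsd_m={self.gsd_m}"
                )
        rmin, rmax = self.canopy_radius_range_m
        if not (0 < rmin <= rmax):
            raise ValueError(f"invalid canopy radius range {self.canopy_radius_range_m}")
        if 2 * rmax > min(self.width_m, self.height_m):
            raise ValueError(
                f"max canopy radius {rmax} m exceeds half the scene extent "
                f"{min(self.width_m, self.height_m) / 2} m"
            )
        if not 0 <= self.shadow_fraction < 1:
            raise ValueError(f"shadow_fraction {self.shadow_fraction} outside [0, 1)")
        if not 0 <= self.sparse_fraction <= 1:
            raise ValueError(f"sparse_fraction {self.sparse_fraction} outside [0, 1]")
        diff = np.abs(np.subtract(self.mean_color_target, self.mean_color_background))
        if diff.max() >= self.mean_color_tolerance:
            raise ValueError(
                "class mean colors differ by "
                f"{diff.max():.1f} DN, >= tolerance {self.mean_color_tolerance}; "
                "the class signal must live in texture, not mean color"
            )

    @property
    def shape_px(self) -> tuple[int, int]:
        return int(round(self.height_m / self.gsd_m)), int(round(self.width_m / self.gsd_m))


@dataclass
class Scene:
    """Co-registered RGB orthomosaic, DEM and reference canopy polygons."""

    rgb: RasterGrid  # 3-band uint8
    dem: RasterGrid  # 1-band float32, metres
    polygons: list[Polygon]
    geotransform: GeoTransform
    crs_id: str
    shadow_mask: np.ndarray | None = None  # rendered cast-shadow pixels (diagnostic)

    def __post_init__(self) -> None:
        if self.rgb.shape != self.dem.shape:
            raise ValueError(f"rgb {self.rgb.shape} and dem {self.dem.shape} shapes differ")
        if self.rgb.geotransform != self.dem.geotransform:
            raise ValueError("rgb and dem geotransforms differ")
        for i, poly in enumerate(self.polygons):
            if not poly.is_valid or poly.area <= 0:
                raise ValueError(f"polygon {i} invalid or degenerate")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape

    def reference_mask(self) -> BinaryMask:
        return rasterize_polygons(self.polygons, self.rgb)

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_raster(out / "ortho_rgb.tif", self.rgb)
        write_raster(out / "dem.tif", self.dem)
        write_polygons(out / "reference_polygons.geojson", self.polygons, self.crs_id)
        if self.shadow_mask is not None:
            write_raster(
                out / "shadow_mask.tif",
                RasterGrid(self.shadow_mask.astype(np.uint8), self.geotransform, self.crs_id),
            )


def _bandlimited_noise(shape: tuple[int, int], params: TextureParams,
                       rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance speckle with a Gaussian spectral envelope.

    White noise is low-passed in the frequency domain by an anisotropic
    Gaussian whose sigmas derive from the grain length; this gives exact
    control of correlation length and orientation without edge artefacts.
    """
    rows, cols = shape
    white = rng.standard_normal(shape).astype(np.float64)
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    theta = np.deg2rad(params.anisotropy_deg)
    # rotate frequency axes so the major grain axis aligns with theta
    fu = fx * np.cos(theta) + fy * np.sin(theta)
    fv = -fx * np.sin(theta) + fy * np.cos(theta)
    ratio = max(params.anisotropy_ratio, 1e-6)
    sigma_u = params.grain_px * np.sqrt(ratio)
    sigma_v = params.grain_px / np.sqrt(ratio)
    envelope = np.exp(-2.0 * np.pi**2 * ((fu * sigma_u) ** 2 + (fv * sigma_v) ** 2))
    fld = np.fft.ifft2(np.fft.fft2(white) * envelope).real
    std = fld.std()
    if std < 1e-12:
        return np.zeros(shape)
    return (fld - fld.mean()) / std


def _star_convex_polygon(center: tuple[float, float], radius: float,
                         rng: np.random.Generator, n_vertices: int = 72) -> Polygon:
    """Irregular crown outline: radial harmonics modulating a circle."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    r = np.ones_like(theta)
    for k in range(2, 7):
        amp = rng.uniform(0.0, 0.25 / k)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        r += amp * np.cos(k * theta + phase)
    r = np.clip(r, 0.35, 1.45) * radius
    x = center[0] + r * np.cos(theta)
    y = center[1] + r * np.sin(theta)
    poly = Polygon(np.column_stack([x, y]))
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def _sample_canopies(cfg: SceneConfig, rng: np.random.Generator) -> list[Polygon]:
    rmin, rmax = cfg.canopy_radius_range_m
    polygons: list[Polygon] = []
    for _ in range(cfg.n_canopies):
        for _attempt in range(50):
            radius = rng.uniform(rmin, rmax)
            margin = radius * 1.5
            if 2 * margin >= cfg.width_m or 2 * margin >= cfg.height_m:
                continue
            cx = rng.uniform(margin, cfg.width_m - margin)
            cy = rng.uniform(margin, cfg.height_m - margin)
            poly = _star_convex_polygon((cx, cy), radius, rng)
            minx, miny, maxx, maxy = poly.bounds
            if minx >= 0 and miny >= 0 and maxx <= cfg.width_m and maxy <= cfg.height_m:
                polygons.append(poly)
                break
    return polygons


def _occluder_shadows(cfg: SceneConfig, rng: np.random.Generator) -> list[Polygon]:
    """Shadow patches thrown by taller off-class vegetation: elongated blobs
    stretched along the sun azimuth, positioned independently of the target
    canopies (they darken canopy interiors and open ground alike)."""
    from shapely import affinity

    lo, hi = cfg.shadow_occluder_size_m
    azim = cfg.shadow_azimuth_deg
    patches = []
    for _ in range(cfg.shadow_occluders):
        length = rng.uniform(lo, hi)
        width = rng.uniform(0.4 * length, 0.8 * length)
        blob = _star_convex_polygon((0.0, 0.0), 1.0, rng, n_vertices=36)
        blob = affinity.scale(blob, xfact=length / 2.0, yfact=width / 2.0, origin=(0, 0))
        blob = affinity.rotate(blob, 90.0 - azim, origin=(0, 0))
        cx = rng.uniform(0.0, cfg.width_m)
        cy = rng.uniform(0.0, cfg.height_m)
        patches.append(affinity.translate(blob, xoff=cx, yoff=cy))
    return patches


def _shift_bool(mask: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Shift a boolean raster by whole pixels, zero-filling exposed edges."""
    out = np.zeros_like(mask)
    rows, cols = mask.shape
    r_src = slice(max(-dr, 0), min(rows - dr, rows))
    r_dst = slice(max(dr, 0), min(rows + dr, rows))
    c_src = slice(max(-dc, 0), min(cols - dc, cols))
    c_dst = slice(max(dc, 0), min(cols + dc, cols))
    out[r_dst, c_dst] = mask[r_src, c_src]
    return out


def _terrain(shape: tuple[int, int], cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    rows, cols = shape
    rr = np.linspace(0.0, 1.0, rows)[:, None]
    cc = np.linspace(0.0, 1.0, cols)[None, :]
    plane = cfg.terrain_slope_m * 0.5 * (rr + cc)
    rough = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=max(rows, cols) / 10.0)
    std = rough.std()
    if std > 1e-12:
        rough = rough / std * (cfg.terrain_relief_m / 2.0)
    else:
        rough = np.zeros(shape)
    return plane + rough


def generate_scene(config: SceneConfig) -> Scene:
    """Render a scene from a config; identical configs give bit-identical scenes."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows, cols = config.shape_px
    gt = GeoTransform.north_up(0.0, config.height_m, config.gsd_m)

    polygons = _sample_canopies(config, rng)
    template = RasterGrid(np.zeros((rows, cols), dtype=np.uint8), gt, _DEFAULT_CRS)
    canopy_mask = rasterize_polygons(polygons, template).values.astype(bool)

    # per-canopy bookkeeping (sparse rendering, shadow crescents) via labels
    labels, n_labels = ndimage.label(canopy_mask)

    tex_bg = _bandlimited_noise((rows, cols), config.texture_background, rng)
    tex_tg = _bandlimited_noise((rows, cols), config.texture_target, rng)
    sparse_field = _bandlimited_noise(
        (rows, cols),
        TextureParams(grain_px=max(config.texture_target.grain_px * 1.5, 3.0), contrast=1.0),
        rng,
    )

    # which rasterized pixels actually carry target texture (sparse canopies
    # interleave ground texture inside the polygon)
    target_pixels = canopy_mask.copy()
    sparse_ids = []
    if config.sparse_fraction > 0 and n_labels > 0:
        n_sparse = int(round(config.sparse_fraction * n_labels))
        sparse_ids = list(rng.choice(np.arange(1, n_labels + 1), size=n_sparse, replace=False))
        thresh = np.quantile(sparse_field, 1.0 - config.sparse_cover)
        dotted = sparse_field >= thresh
        for lab in sparse_ids:
            region = labels == lab
            target_pixels[region & ~dotted] = False

    rgb = np.empty((3, rows, cols), dtype=np.float64)
    for b in range(3):
        base = np.where(target_pixels, config.mean_color_target[b],
                        config.mean_color_background[b]).astype(np.float64)
        tex = np.where(target_pixels,
                       tex_tg * config.texture_target.contrast,
                       tex_bg * config.texture_background.contrast)
        rgb[b] = base + tex

    # cast shadow: a self-shadowed border crescent on the down-sun side of each
    # canopy plus the canopy silhouette projected onto the adjacent ground, so
    # darkness itself carries both class labels and is not a canopy-exclusive cue
    shadow = np.zeros((rows, cols), dtype=bool)
    if config.shadow_fraction > 0 and n_labels > 0:
        azim = np.deg2rad(config.shadow_azimuth_deg)
        direction = np.array([np.sin(azim), np.cos(azim)])  # (d_col, d_row) unit vector
        dist_in = ndimage.distance_transform_edt(canopy_mask)
        objects = ndimage.find_objects(labels)
        for lab, slc in enumerate(objects, start=1):
            if slc is None:
                continue
            region = labels[slc] == lab
            rr_idx, cc_idx = np.nonzero(region)
            crow, ccol = rr_idx.mean(), cc_idx.mean()
            side = (cc_idx - ccol) * direction[0] + (rr_idx - crow) * direction[1] > 0
            d = dist_in[slc][region]
            # erosion depth chosen so the crescent holds ~shadow_fraction of the area
            t = np.quantile(d, min(2.0 * config.shadow_fraction, 1.0))
            sel = side & (d <= t)
            sub = shadow[slc]
            sub[rr_idx[sel], cc_idx[sel]] = True
            shadow[slc] = sub
        cast_px = max(int(round(config.shadow_length_m / config.gsd_m)), 1)
        cast = np.zeros_like(canopy_mask)
        for frac in (1.0 / 3.0, 2.0 / 3.0, 1.0):
            dc = int(round(direction[0] * cast_px * frac))
            dr = int(round(direction[1] * cast_px * frac))
            cast |= _shift_bool(canopy_mask, dr, dc)
        shadow |= cast & ~canopy_mask
        if config.shadow_occluders > 0:
            occluders = _occluder_shadows(config, rng)
            shadow |= rasterize_polygons(occluders, template).values.astype(bool)
        rgb[:, shadow] *= config.shadow_darkness

    rgb_u8 = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    # DEM: terrain + tapered canopy-height bumps + rough canopy surface
    dem = _terrain((rows, cols), config, rng)
    if n_labels > 0:
        dist_in = ndimage.distance_transform_edt(canopy_mask)
        taper_px = max(0.5 / config.gsd_m, 1.0)  # ~0.5 m edge taper
        bump = np.minimum(dist_in / taper_px, 1.0) * config.canopy_height_m
        canopy_rough = ndimage.gaussian_filter(
            rng.standard_normal((rows, cols)), sigma=3.0)
        crstd = canopy_rough.std()
        if crstd > 1e-12:
            bump += (canopy_rough / crstd * config.dem_noise_m) * (dist_in > 0)
        bump = np.maximum(bump, 0.0)
        if shadow.any() and config.shadow_dem_attenuation > 0:
            # dense matching breaks down in deep shadow: relief collapses
            # toward the terrain and picks up extra reconstruction noise
            bump[shadow] *= 1.0 - config.shadow_dem_attenuation
            sn = ndimage.gaussian_filter(rng.standard_normal((rows, cols)), sigma=2.0)
            snstd = sn.std()
            if snstd > 1e-12:
                dem[shadow] += sn[shadow] / snstd * config.shadow_dem_noise_m
        dem = dem + bump

    scene = Scene(
        rgb=RasterGrid(rgb_u8, gt, _DEFAULT_CRS),
        dem=RasterGrid(dem.astype(np.float32), gt, _DEFAULT_CRS),
        polygons=polygons,
        geotransform=gt,
        crs_id=_DEFAULT_CRS,
        shadow_mask=shadow,
    )
    logger.info("generated scene %dx%d px, %d canopies, cover %.3f",
                rows, cols, len(polygons), scene_cover_fraction(scene))
    return scene


def scene_cover_fraction(scene: Scene) -> float:
    """Fraction of scene pixels inside the rasterized reference polygons."""
    if not scene.polygons:
        return 0.0
    mask = scene.reference_mask().values
    return float(mask.mean())
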