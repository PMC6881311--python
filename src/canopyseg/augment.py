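"""Joint geometric augmentation of predictor tiles and masks.

Each training tile is perturbed by a random combination of shear (0-0.2 rad),
rotation in 20-degree steps, per-axis shift (up to 15% of the tile edge) and
horizontal/vertical flips.  The identical geometry is applied to every
predictor channel (bilinear) and to the mask (nearest neighbour, so labels
stay binary).  Besides inflating the training set, this strips acquisition-
specific directional cues such as a fixed sun azimuth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .tiling import Tile

__all__ = ["AugmentConfig", "TransformDescriptor", "sample_transform", "apply_transform"]


@dataclass(frozen=True)
class AugmentConfig:
    shear_range_rad: tuple[float, float] = (0.0, 0.2)
    rotation_step_deg: int = 20
    shift_range_frac: tuple[float, float] = (0.0, 0.15)
    allow_hflip: bool = True
    allow_vflip: bool = True
    fill_mode: str = "reflect"

    def __post_init__(self) -> None:
        lo, hi = self.shear_range_rad
        if not (0.0 <= lo <= hi <= 0.2 + 1e-12):
            raise ValueError(f"shear range {self.shear_range_rad} outside [0, 0.2] rad")
        lo, hi = self.shift_range_frac
        if not (0.0 <= lo <= hi <= 0.15 + 1e-12):
            raise ValueError(f"shift range {self.shift_range_frac} outside [0, 0.15]")
        if self.rotation_step_deg <= 0 or 360 % self.rotation_step_deg != 0:
            raise ValueError(f"rotation step {self.rotation_step_deg} must divide 360")

    @classmethod
    def identity(cls) -> "AugmentConfig":
        return cls(shear_range_rad=(0.0, 0.0), rotation_step_deg=360,
                   shift_range_frac=(0.0, 0.0), allow_hflip=False, allow_vflip=False)


@dataclass(frozen=True)
class TransformDescriptor:
    shear_rad: float = 0.0
    rotation_deg: int = 0
    shift_frac: tuple[float, float] = (0.0, 0.0)  # (row, col), signed
    hflip: bool = False
    vflip: bool = False

    @property
    def is_identity(self) -> bool:
        return (self.shear_rad == 0.0 and self.rotation_deg % 360 == 0
                and self.shift_frac == (0.0, 0.0) and not self.hflip and not self.vflip)


def sample_transform(config: AugmentConfig, rng: np.random.Generator) -> TransformDescriptor:
    """Draw a transform uniformly from the configured ranges and sets."""
    shear = float(rng.uniform(*config.shear_range_rad))
    n_steps = 360 // config.rotation_step_deg
    rotation = int(rng.integers(0, n_steps)) * config.rotation_step_deg
    lo, hi = config.shift_range_frac
    # shift magnitude within range, independent random sign per axis
    shifts = tuple(float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])) for _ in range(2))
    hflip = bool(config.allow_hflip and rng.integers(0, 2))
    vflip = bool(config.allow_vflip and rng.integers(0, 2))
    return TransformDescriptor(shear_rad=shear, rotation_deg=rotation,
                               shift_frac=shifts, hflip=hflip, vflip=vflip)


def transform_matrix(t: TransformDescriptor, tile_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward affine (A, offset) in (row, col) coordinates about the tile center.

    Output pixel p maps from input pixel A_inv @ (p - center - shift) + center.
    The forward map is flip . rotation . shear applied about the center, then
    the shift.
    """
    theta = np.deg2rad(t.rotation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    shear = np.array([[1.0, t.shear_rad], [0.0, 1.0]])
    flip = np.diag([-1.0 if t.vflip else 1.0, -1.0 if t.hflip else 1.0])
    A = flip @ rot @ shear
    center = np.array([(tile_px - 1) / 2.0, (tile_px - 1) / 2.0])
    shift = np.array(t.shift_frac) * tile_px
    offset = center + shift - A @ center
    return A, offset


def _warp(channel: np.ndarray, A: np.ndarray, offset: np.ndarray,
          order: int, mode: str) -> np.ndarray:
    # ndimage.affine_transform maps output coords through (matrix, offset) to
    # input coords, i.e. it applies the *inverse* of our forward map.
    A_inv = np.linalg.inv(A)
    inv_offset = -A_inv @ offset
    return ndimage.affine_transform(channel, A_inv, offset=inv_offset, order=order,
                                    mode=mode, prefilter=False)


def apply_transform(tile: Tile, t: TransformDescriptor, config: AugmentConfig) -> Tile:
    """Warp predictors (bilinear) and mask (nearest) by the same geometry."""
    if t.is_identity:
        return Tile(predictors=tile.predictors.copy(), mask=tile.mask.copy(),
                    origin=tile.origin)
    tile_px = tile.mask.shape[0]
    A, offset = transform_matrix(t, tile_px)
    predictors = np.stack([
        _warp(tile.predictors[c].astype(np.float32), A, offset, order=1, mode=config.fill_mode)
        for c in range(tile.predictors.shape[0])
    ])
    mask = _warp(tile.mask.astype(np.float32), A, offset, order=0, mode=config.fill_mode)
    mask = (mask > 0.5).astype(np.uint8)
    return Tile(predictors=predictors, mask=mask, origin=tile.origin)
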