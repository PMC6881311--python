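import numpy as np
import pytest

from canopyseg.synthetic_scene import SceneConfig, generate_scene
from canopyseg.tiling import TileSpec, sample_tiles
from canopyseg.unet_model import UNet, UNetSpec


def small_scene_config(seed: int = 42, **overrides) -> SceneConfig:
    """A 24 m x 24 m scene (800x800 px) that generates in ~1 s."""
    kwargs = dict(
        width_m=24.0,
        height_m=24.0,
        gsd_m=0.03,
        n_canopies=8,
        canopy_radius_range_m=(1.0, 3.0),
        seed=seed,
    )
    kwargs.update(overrides)
    return SceneConfig(**kwargs)


@pytest.fixture(scope="session")
def small_scene():
    return generate_scene(small_scene_config())


@pytest.fixture(scope="session")
def small_tileset(small_scene):
    # 4 m spacing still satisfies the non-overlap guarantee (tile edge 3.84 m)
    spec = TileSpec(grid_spacing_m=4.0, seed=7)
    return sample_tiles(small_scene, small_scene.reference_mask(), spec)


@pytest.fixture(scope="session")
def tiny_model():
    """A small untrained net for shape/determinism checks."""
    return UNet(UNetSpec(levels=3, base_filters=4), seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
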