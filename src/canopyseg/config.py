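"""Run configuration: one YAML file, one global seed, one output directory.

The global seed is fanned out deterministically to every stochastic stage
(scene synthesis, tile sampling/splitting, weight initialization, training
batches/augmentation) through named ``numpy`` seed sequences, so a run is
reproducible end to end from a single integer.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import numpy as np
import yaml

from .augment import AugmentConfig
from .synthetic_scene import SceneConfig, TextureParams
from .tiling import TileSpec
from .training import TrainConfig
from .unet_model import UNetSpec

__all__ = ["RunConfig", "stage_seed", "desk_profile"]

_STAGES = {"scene": 0, "tiles": 1, "model": 2, "train": 3, "shadow_scene": 4}


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed via a named seed sequence."""
    ss = np.random.SeedSequence([int(global_seed), _STAGES[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


def _coerce(cls, value):
    """Build a (possibly nested) dataclass from a plain mapping."""
    if value is None or not is_dataclass(cls):
        return value
    if is_dataclass(value):
        return value
    known = {f.name for f in fields(cls)}
    unknown = set(value) - known
    if unknown:
        raise TypeError(f"unknown fields {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name not in value:
            continue
        v = value[f.name]
        if f.name in ("texture_target", "texture_background"):
            v = TextureParams(**v) if isinstance(v, dict) else v
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class RunConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    tiles: TileSpec = field(default_factory=TileSpec)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    model: UNetSpec = field(default_factory=UNetSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval_threshold: float = 0.5
    map_tile_px: int = 128
    seed: int = 0
    out_dir: str = "runs/default"

    def with_seed(self, seed: int) -> "RunConfig":
        """Return a copy with the global seed fanned out to every stage."""
        from dataclasses import replace

        return replace(
            self,
            seed=seed,
            scene=replace(self.scene, seed=stage_seed(seed, "scene")),
            tiles=replace(self.tiles, seed=stage_seed(seed, "tiles")),
            train=replace(self.train, seed=stage_seed(seed, "train")),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        kwargs = {}
        for f in fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if f.name in ("scene", "tiles", "augment", "model", "train"):
                try:
                    v = _coerce(f.type if is_dataclass(f.type) else
                                {"scene": SceneConfig, "tiles": TileSpec,
                                 "augment": AugmentConfig, "model": UNetSpec,
                                 "train": TrainConfig}[f.name], v)
                except TypeError as exc:
                    raise ValueError(f"invalid config section {f.name!r}: {exc}") from exc
            kwargs[f.name] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def desk_profile(seed: int = 0, out_dir: str = "runs/desk") -> RunConfig:
    """Single-CPU profile: the reference data model with a 4-level U-net and
    the training schedule scaled down to minutes (see docs/methods.md)."""
    cfg = RunConfig(
        model=UNetSpec(levels=4),
        train=TrainConfig(learning_rate=3e-4, epochs=10, steps_per_epoch=40),
        out_dir=out_dir,
    )
    return cfg.with_seed(seed)
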