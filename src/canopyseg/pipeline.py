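"""End-to-end run: simulate -> tiles -> train -> evaluate -> map.

Every stage's artifacts (rasters, tile manifest, training log, evaluation
report, segmentation map and a run manifest with seeds and digests) are
written under the configured output directory, so each intermediate can be
inspected or re-read by the module that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

from .config import RunConfig, stage_seed
from .evaluation import stratified_accuracy
from .mapping import map_extract
from .synthetic_scene import generate_scene
from .tiling import sample_tiles
from .training import train
from .unet_model import UNet, save_weights

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"seed": config.seed, "stages": {}}
    stage = "simulate"
    try:
        t0 = time.time()
        scene = generate_scene(config.scene)
        scene.write(out / "scene")
        mask = scene.reference_mask()
        manifest["stages"]["simulate"] = {
            "seconds": round(time.time() - t0, 1),
            "n_canopies": len(scene.polygons),
            "cover": float(mask.values.mean()),
            "ortho_digest": _digest(out / "scene" / "ortho_rgb.tif"),
        }

        stage = "tiles"
        t0 = time.time()
        tiles = sample_tiles(scene, mask, config.tiles)
        manifest["stages"]["tiles"] = {
            "seconds": round(time.time() - t0, 1),
            "n_train": len(tiles.train),
            "n_holdoff": len(tiles.holdoff),
            "n_validation": len(tiles.validation),
        }

        stage = "train"
        t0 = time.time()
        model = UNet(config.model, seed=stage_seed(config.seed, "model"))
        model, log = train(model, tiles, config.augment, config.train,
                           log_path=out / "train_log.tsv")
        save_weights(model, out / "weights.npz")
        manifest["stages"]["train"] = {
            "seconds": round(time.time() - t0, 1),
            "best_epoch": log.best_epoch,
            "final_holdoff_accuracy": log.records[-1].holdoff_accuracy,
        }

        stage = "evaluate"
        t0 = time.time()
        report = stratified_accuracy(tiles.validation, model,
                                     threshold=config.eval_threshold)
        report.write(out / "evaluation.json")
        report.write(out / "evaluation.tsv")
        manifest["stages"]["evaluate"] = {
            "seconds": round(time.time() - t0, 1),
            "accuracy": report.accuracy,
            "bias": report.bias,
        }

        stage = "map"
        t0 = time.time()
        seg_map = map_extract(scene, model, tile_px=config.map_tile_px,
                              threshold=config.eval_threshold)
        seg_map.write(out / "map")
        manifest["stages"]["map"] = {
            "seconds": round(time.time() - t0, 1),
            "mapped_cover": float(seg_map.labels.mean()),
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("run complete: %s", out)
    return out
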