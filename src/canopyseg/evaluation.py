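"""Cover-stratified accuracy and prediction bias on the independent validation tiles.

Validation tiles are grouped by target-class cover into three strata —
0-33%, 33-66% and 66-100% — before accuracy is averaged, so that the summary
is not dominated by the (typically far more frequent) low-cover tiles.  Bias
is the mean residual between predicted and reference cover: positive values
mean the model over-predicts the target class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .tiling import Tile, tile_cover
from .unet_model import UNet, dice_coefficient

__all__ = ["EvaluationReport", "pixel_accuracy", "assign_stratum", "stratified_accuracy"]

STRATA_BOUNDS = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0)


def pixel_accuracy(pred_labels: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of pixels where the predicted label equals the reference."""
    pred_labels = np.asarray(pred_labels)
    truth = np.asarray(truth)
    if pred_labels.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred_labels.shape} vs truth {truth.shape}")
    return float((pred_labels.astype(bool) == truth.astype(bool)).mean())


def assign_stratum(cover: float) -> int:
    """Stratum 1 for cover in [0, 1/3), 2 for [1/3, 2/3), 3 for [2/3, 1]."""
    if not 0.0 <= cover <= 1.0:
        raise ValueError(f"cover {cover} outside [0, 1]")
    if cover < STRATA_BOUNDS[1]:
        return 1
    if cover < STRATA_BOUNDS[2]:
        return 2
    return 3


@dataclass
class EvaluationReport:
    strata_bounds: tuple = STRATA_BOUNDS
    per_stratum_accuracy: dict[int, float] = field(default_factory=dict)
    n_tiles_per_stratum: dict[int, int] = field(default_factory=dict)
    accuracy: float = float("nan")       # unweighted mean over occupied strata
    accuracy_tile_weighted: float = float("nan")
    bias: float = float("nan")           # mean tile-level cover residual
    bias_per_pixel: float = float("nan")  # mean per-pixel residual (prob - truth)
    mean_dice: float = float("nan")
    n_tiles: int = 0

    def __post_init__(self) -> None:
        for acc in self.per_stratum_accuracy.values():
            if not 0.0 <= acc <= 1.0:
                raise ValueError(f"stratum accuracy {acc} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "strata_bounds": list(self.strata_bounds),
            "per_stratum_accuracy": {str(k): v for k, v in self.per_stratum_accuracy.items()},
            "n_tiles_per_stratum": {str(k): v for k, v in self.n_tiles_per_stratum.items()},
            "accuracy": self.accuracy,
            "accuracy_tile_weighted": self.accuracy_tile_weighted,
            "bias": self.bias,
            "bias_per_pixel": self.bias_per_pixel,
            "mean_dice": self.mean_dice,
            "n_tiles": self.n_tiles,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(
            strata_bounds=tuple(d["strata_bounds"]),
            per_stratum_accuracy={int(k): v for k, v in d["per_stratum_accuracy"].items()},
            n_tiles_per_stratum={int(k): v for k, v in d["n_tiles_per_stratum"].items()},
            accuracy=d["accuracy"],
            accuracy_tile_weighted=d["accuracy_tile_weighted"],
            bias=d["bias"],
            bias_per_pixel=d["bias_per_pixel"],
            mean_dice=d["mean_dice"],
            n_tiles=d["n_tiles"],
        )

    def write(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
            return
        lines = ["metric\tvalue",
                 f"accuracy_pct\t{self.accuracy * 100:.1f}",
                 f"bias\t{self.bias:.4f}"]
        for k in sorted(self.per_stratum_accuracy):
            lo, hi = self.strata_bounds[k - 1], self.strata_bounds[k]
            lines.append(f"accuracy_cover_{lo:.2f}_{hi:.2f}\t{self.per_stratum_accuracy[k]:.4f}"
                         f"\t(n={self.n_tiles_per_stratum[k]})")
        lines.append(f"mean_dice\t{self.mean_dice:.4f}")
        path.write_text("\n".join(lines) + "\n")


def stratified_accuracy(tiles: list[Tile], model: UNet, threshold: float = 0.5,
                        batch: int = 8) -> EvaluationReport:
    """Evaluate a model on validation tiles, stratifying accuracy by reference cover.

    Per-stratum accuracy is the mean tile-level pixel accuracy of the stratum's
    tiles; the summary accuracy is the unweighted mean over occupied strata
    (empty strata are excluded and reported absent).  Bias is the mean of
    (predicted cover - reference cover) over all validation tiles.
    """
    if not tiles:
        raise ValueError("validation set is empty")
    accs: dict[int, list[float]] = {1: [], 2: [], 3: []}
    residuals = []
    pixel_residuals = []
    dices = []
    all_accs = []
    for i in range(0, len(tiles), batch):
        chunk = tiles[i:i + batch]
        x = np.stack([np.moveaxis(t.predictors, 0, -1) for t in chunk]).astype(np.float32)
        probs = model.predict(x)
        labels = probs >= threshold
        for j, tile in enumerate(chunk):
            truth = tile.mask.astype(bool)
            acc = float((labels[j] == truth).mean())
            stratum = assign_stratum(tile_cover(tile.mask))
            accs[stratum].append(acc)
            all_accs.append(acc)
            residuals.append(float(labels[j].mean()) - float(truth.mean()))
            pixel_residuals.append(float((probs[j] - truth).mean()))
            dices.append(dice_coefficient(labels[j].astype(float), truth.astype(float),
                                          smooth=1.0))
    per_stratum = {k: float(np.mean(v)) for k, v in accs.items() if v}
    counts = {k: len(v) for k, v in accs.items() if v}
    return EvaluationReport(
        per_stratum_accuracy=per_stratum,
        n_tiles_per_stratum=counts,
        accuracy=float(np.mean(list(per_stratum.values()))),
        accuracy_tile_weighted=float(np.mean(all_accs)),
        bias=float(np.mean(residuals)),
        bias_per_pixel=float(np.mean(pixel_residuals)),
        mean_dice=float(np.mean(dices)),
        n_tiles=len(tiles),
    )
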