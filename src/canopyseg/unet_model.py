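"""U-net encoder-decoder for binary canopy segmentation, in pure NumPy.

The architecture is the classic 5-level U-net: repeated 3x3 same-padding
convolutions with ReLU, 2x2 max pooling between levels, feature depth doubling
with each pooling, a mirrored decoder of 2x2 up-convolutions with skip
concatenation from the matching encoder stage, and a 1x1 convolution with a
sigmoid activation producing a per-pixel presence probability.  Forward and
backward passes are implemented explicitly (shifted-GEMM convolutions), so the
network trains on a plain CPU without a deep-learning framework.

The dice coefficient ``(2*sum(p*t)+s) / (sum(p)+sum(t)+s)`` doubles as the
training loss (``1 - dice``): it is insensitive to the large class imbalance
of sparse canopy masks, unlike per-pixel cross-entropy.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "UNetSpec",
    "SegmentationOutput",
    "UNet",
    "build_unet",
    "dice_coefficient",
    "dice_loss",
    "predict_tile",
    "save_weights",
    "load_weights",
]


@dataclass(frozen=True)
class UNetSpec:
    levels: int = 5
    kernel: int = 3
    pool: int = 2
    base_filters: int = 16
    convs_per_level: int = 2
    in_channels: int = 4
    out_threshold: float = 0.5
    # initial bias of the output layer: the logit of the expected target-class
    # prior, so the net starts from a plausible background-dominated prediction
    # instead of collapsing to all-ones in the first dice-loss steps
    head_bias_init: float = -1.1

    def __post_init__(self) -> None:
        if self.levels < 1 or self.kernel % 2 != 1 or self.pool < 2:
            raise ValueError(f"invalid architecture spec {self}")
        if self.base_filters < 1 or self.convs_per_level < 1 or self.in_channels < 1:
            raise ValueError(f"invalid architecture spec {self}")

    def filters_at(self, level: int) -> int:
        """Feature depth at encoder level (1-based): doubles with each pooling."""
        return self.base_filters * self.pool ** (level - 1)

    def bottleneck_size(self, tile_px: int) -> int:
        factor = self.pool ** (self.levels - 1)
        if tile_px % factor != 0:
            raise ValueError(
                f"tile size {tile_px} not divisible by pool^(levels-1) = {factor}"
            )
        return tile_px // factor


@dataclass
class SegmentationOutput:
    probabilities: np.ndarray  # (h, w) in [0, 1]
    threshold: float = 0.5

    @property
    def labels(self) -> np.ndarray:
        return (self.probabilities >= self.threshold).astype(np.uint8)


def dice_coefficient(pred: np.ndarray, truth: np.ndarray, smooth: float = 1.0) -> float:
    """Soft overlap 2|A.B|/(|A|+|B|) with an additive smoothing guard."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    inter = float((pred * truth).sum())
    total = float(pred.sum() + truth.sum())
    return (2.0 * inter + smooth) / (total + smooth)


def dice_loss(pred: np.ndarray, truth: np.ndarray, smooth: float = 1.0) -> float:
    return 1.0 - dice_coefficient(pred, truth, smooth)


# ---------------------------------------------------------------------------
# layers (NHWC, float32)


class _Conv:
    """k x k same-padding convolution as k^2 shifted GEMMs."""

    def __init__(self, k: int, cin: int, cout: int, rng: np.random.Generator):
        fan_in = k * k * cin
        self.W = (rng.standard_normal((k, k, cin, cout)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(cout, dtype=np.float32)
        self.k = k
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp = None
        # persistent padded input-gradient accumulator, reused across steps
        self._dxp_buf = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k, pad = self.k, self.k // 2
        n, h, w, cin = x.shape
        cout = self.W.shape[-1]
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0))) if pad else x
        y = np.empty((n * h * w, cout), dtype=np.float32)
        y[:] = self.b
        for di in range(k):
            for dj in range(k):
                xs = np.ascontiguousarray(xp[:, di:di + h, dj:dj + w, :]).reshape(-1, cin)
                y += xs @ self.W[di, dj]
        self._xp = xp if train else None
        self._in_shape = (n, h, w, cin)
        return y.reshape(n, h, w, cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, pad = self.k, self.k // 2
        n, h, w, cin = self._in_shape
        cout = self.W.shape[-1]
        dyf = dy.reshape(-1, cout)
        self.db += dyf.sum(axis=0)
        shape = (n, h + 2 * pad, w + 2 * pad, cin)
        if self._dxp_buf is None or self._dxp_buf.shape != shape:
            self._dxp_buf = np.empty(shape, dtype=np.float32)
        dxp = self._dxp_buf
        dxp[:] = 0.0
        for di in range(k):
            for dj in range(k):
                xs = np.ascontiguousarray(
                    self._xp[:, di:di + h, dj:dj + w, :]).reshape(-1, cin)
                self.dW[di, dj] += xs.T @ dyf
                dxp[:, di:di + h, dj:dj + w, :] += (dyf @ self.W[di, dj].T).reshape(
                    n, h, w, cin)
        self._xp = None
        if pad:
            return dxp[:, pad:-pad, pad:-pad, :]
        return dxp


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class _MaxPool:
    def __init__(self, p: int):
        self.p = p

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        p = self.p
        n, h, w, c = x.shape
        xr = x.reshape(n, h // p, p, w // p, p, c)
        y = xr.max(axis=(2, 4))
        if train:
            mask = xr == y[:, :, None, :, None, :]
            self._mask = mask
            self._count = mask.sum(axis=(2, 4), dtype=np.float32)
            self._shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        # gradient split evenly among tied maxima keeps the total flow exact
        dyr = (dy / self._count)[:, :, None, :, None, :]
        dx = (self._mask * dyr).reshape(self._shape)
        self._mask = self._count = None
        return dx.astype(np.float32)


class _UpConv:
    """p x p transposed convolution with stride p (the U-net 'up-convolution')."""

    def __init__(self, p: int, cin: int, cout: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((p, p, cin, cout)) * np.sqrt(2.0 / cin)).astype(
            np.float32
        )
        self.b = np.zeros(cout, dtype=np.float32)
        self.p = p
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        p = self.p
        n, h, w, cin = x.shape
        cout = self.W.shape[-1]
        xf = x.reshape(-1, cin)
        y = np.empty((n, h * p, w * p, cout), dtype=np.float32)
        for di in range(p):
            for dj in range(p):
                y[:, di::p, dj::p, :] = (xf @ self.W[di, dj] + self.b).reshape(n, h, w, cout)
        if train:
            self._x = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        p = self.p
        n, h, w, cin = self._x.shape
        xf = self._x.reshape(-1, cin)
        dx = np.zeros((n * h * w, cin), dtype=np.float32)
        for di in range(p):
            for dj in range(p):
                dyf = np.ascontiguousarray(dy[:, di::p, dj::p, :]).reshape(-1, self.W.shape[-1])
                self.dW[di, dj] += xf.T @ dyf
                self.db += dyf.sum(axis=0)
                dx += dyf @ self.W[di, dj].T
        self._x = None
        return dx.reshape(n, h, w, cin)


# ---------------------------------------------------------------------------


class UNet:
    """Model handle: parameters plus explicit forward/backward passes."""

    def __init__(self, spec: UNetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        s = spec
        self.enc_blocks = []  # per level: list of (_Conv, _ReLU)
        cin = s.in_channels
        for level in range(1, s.levels + 1):
            cout = s.filters_at(level)
            block = []
            for _ in range(s.convs_per_level):
                block.append((_Conv(s.kernel, cin, cout, rng), _ReLU()))
                cin = cout
            self.enc_blocks.append(block)
        self.pools = [_MaxPool(s.pool) for _ in range(s.levels - 1)]
        self.upconvs = []
        self.dec_blocks = []
        for level in range(s.levels - 1, 0, -1):
            cout = s.filters_at(level)
            self.upconvs.append(_UpConv(s.pool, cin, cout, rng))
            block = []
            bcin = cout * 2  # concatenated skip
            for _ in range(s.convs_per_level):
                block.append((_Conv(s.kernel, bcin, cout, rng), _ReLU()))
                bcin = cout
            self.dec_blocks.append(block)
            cin = cout
        self.head = _Conv(1, cin, 1, rng)
        self.head.b[:] = spec.head_bias_init
        self._probs = None

    # -- introspection -----------------------------------------------------

    @property
    def encoder_depths(self) -> list[int]:
        return [self.spec.filters_at(k) for k in range(1, self.spec.levels + 1)]

    def parameters(self):
        layers = [c for blk in self.enc_blocks for c, _ in blk]
        layers += self.upconvs
        layers += [c for blk in self.dec_blocks for c, _ in blk]
        layers.append(self.head)
        for i, layer in enumerate(layers):
            yield f"layer{i:02d}.W", layer, "W"
            yield f"layer{i:02d}.b", layer, "b"

    def get_weights(self) -> dict[str, np.ndarray]:
        return {name: getattr(layer, attr).copy() for name, layer, attr in self.parameters()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for name, layer, attr in self.parameters():
            getattr(layer, attr)[...] = weights[name]

    def zero_grads(self) -> None:
        for _, layer, attr in self.parameters():
            grad = getattr(layer, "d" + attr)
            grad[...] = 0.0

    # -- passes ------------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[-1] != self.spec.in_channels:
            raise ValueError(
                f"expected (n, h, w, {self.spec.in_channels}) input, got {x.shape}"
            )
        self.spec.bottleneck_size(x.shape[1])
        self.spec.bottleneck_size(x.shape[2])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map (n, h, w, in_channels) predictors to (n, h, w) probabilities."""
        self._check_input(x)
        x = np.ascontiguousarray(x, dtype=np.float32)
        skips = []
        for level in range(self.spec.levels):
            for conv, relu in self.enc_blocks[level]:
                x = relu.forward(conv.forward(x, train), train)
            if level < self.spec.levels - 1:
                skips.append(x)
                x = self.pools[level].forward(x, train)
        self._concat_channels = []
        for i, (up, block) in enumerate(zip(self.upconvs, self.dec_blocks)):
            x = up.forward(x, train)
            skip = skips[-(i + 1)]
            self._concat_channels.append(skip.shape[-1])
            x = np.concatenate([skip, x], axis=-1)
            for conv, relu in block:
                x = relu.forward(conv.forward(x, train), train)
        z = self.head.forward(x, train)[..., 0]
        probs = expit(z.astype(np.float64))
        if train:
            self._probs = probs
        return probs

    def backward_dice(self, truth: np.ndarray, smooth: float = 1.0,
                      aggregate: str = "sample") -> float:
        """Backprop of the dice loss from the cached forward; returns the loss.

        ``aggregate="sample"`` averages one dice term per tile (so tiles with
        little or no canopy contribute a well-scaled gradient of their own);
        ``"batch"`` uses a single dice over the pooled batch pixels.
        """
        p = self._probs
        if p is None:
            raise RuntimeError("call forward(train=True) before backward_dice")
        t = np.asarray(truth, dtype=np.float64)
        if t.shape != p.shape:
            raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
        if aggregate == "sample":
            axes = tuple(range(1, p.ndim))
            inter = (p * t).sum(axis=axes, keepdims=True)
            denom = p.sum(axis=axes, keepdims=True) + t.sum(axis=axes, keepdims=True) + smooth
            dice_each = (2.0 * inter + smooth) / denom
            dice = float(dice_each.mean())
            # d(1-dice_i)/dp averaged over the batch
            dp = -(2.0 * t * denom - (2.0 * inter + smooth)) / denom**2 / p.shape[0]
        elif aggregate == "batch":
            inter = (p * t).sum()
            denom = p.sum() + t.sum() + smooth
            dice = (2.0 * inter + smooth) / denom
            # d(1-dice)/dp = -(2t*denom - (2*inter+smooth)) / denom^2
            dp = -(2.0 * t * denom - (2.0 * inter + smooth)) / denom**2
        else:
            raise ValueError(f"unknown dice aggregate {aggregate!r}")
        dz = (dp * p * (1.0 - p)).astype(np.float32)[..., None]
        dx = self.head.backward(dz)
        self._pending: dict[int, np.ndarray] = {}
        for i in range(len(self.dec_blocks) - 1, -1, -1):
            for conv, relu in reversed(self.dec_blocks[i]):
                dx = conv.backward(relu.backward(dx))
            nskip = self._concat_channels[i]
            dskip, dup = dx[..., :nskip], dx[..., nskip:]
            dx = self.upconvs[i].backward(np.ascontiguousarray(dup))
            self._pending[i] = dskip
        # walk encoder backwards, adding skip gradients at their levels
        for level in range(self.spec.levels - 1, -1, -1):
            if level < self.spec.levels - 1:
                dx = self.pools[level].backward(dx)
                # decoder stage i consumed skip from encoder level (levels-2-i)
                i = self.spec.levels - 2 - level
                dx = dx + self._pending.pop(i)
            for conv, relu in reversed(self.enc_blocks[level]):
                dx = conv.backward(relu.backward(dx))
        self._probs = None
        return float(1.0 - dice)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)


def build_unet(spec: UNetSpec, seed: int = 0) -> UNet:
    """Construct a seeded, randomly initialized U-net from an architecture spec."""
    return UNet(spec, seed=seed)


def predict_tile(model: UNet, predictors: np.ndarray,
                 threshold: float | None = None) -> SegmentationOutput:
    """Segment one (in_channels, h, w) predictor tile."""
    predictors = np.asarray(predictors, dtype=np.float32)
    if predictors.ndim != 3 or predictors.shape[0] != model.spec.in_channels:
        raise ValueError(
            f"expected ({model.spec.in_channels}, h, w) predictors, got {predictors.shape}"
        )
    x = np.moveaxis(predictors, 0, -1)[None]
    probs = model.predict(x)[0]
    return SegmentationOutput(
        probabilities=probs,
        threshold=model.spec.out_threshold if threshold is None else threshold,
    )


def save_weights(model: UNet, path) -> None:
    """Serialize weights to one .npz file with the architecture spec embedded."""
    payload = model.get_weights()
    payload["__spec__"] = np.frombuffer(
        json.dumps(asdict(model.spec)).encode(), dtype=np.uint8
    )
    np.savez_compressed(path, **payload)


def load_weights(path, spec: UNetSpec | None = None) -> UNet:
    """Rebuild a model from a weights file; verifies spec compatibility."""
    with np.load(path) as data:
        stored = UNetSpec(**json.loads(bytes(data["__spec__"]).decode()))
        if spec is not None and spec != stored:
            raise ValueError(f"weights were trained with {stored}, requested {spec}")
        model = UNet(stored, seed=0)
        model.set_weights({k: data[k] for k in data.files if k != "__spec__"})
    return model
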