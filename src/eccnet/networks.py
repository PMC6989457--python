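"""The eccentricity-dependent network (ENN) and its single-resolution CNN control.

The ENN applies one shared 4-layer conv/pool stack to every channel of the
centered-crop pyramid, max-pools the resulting feature vectors element-wise
across scale channels, and classifies the pooled vector with a fully
connected layer.  The CNN control uses the identical layer parameters on a
single image of the whole field, downsampled to the resolution of the
ENN's 5th scale channel (index 4), with no scale pooling.

Both are plain-NumPy models trained with Adam on softmax cross-entropy;
everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nnops import Adam, Conv2d, Linear, MaxPool2d, ReLU, softmax_cross_entropy
from .pyramid import CropPyramid, PyramidSpec, channel_resolution, crop_spans, sample_pyramid
from .stimuli import FieldCalibration, VisualFieldImage, resize_raster

__all__ = [
    "LayerSpec",
    "ENNConfig",
    "CNNConfig",
    "ENN",
    "CNN",
    "TrainConfig",
    "TrainingError",
    "train",
    "default_layers",
    "cnn_config_from_enn",
    "pyramid_input",
    "cnn_input",
    "ENNExtractor",
    "CNNExtractor",
    "save_weights",
    "load_weights",
]


@dataclass(frozen=True)
class LayerSpec:
    conv_kernel: int
    conv_stride: int
    pool_kernel: int
    pool_stride: int
    n_filters: int

    def __post_init__(self) -> None:
        for name in ("conv_kernel", "conv_stride", "pool_kernel", "pool_stride", "n_filters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


def default_layers(filters: tuple[int, int, int, int] = (16, 16, 32, 32)) -> list[LayerSpec]:
    """The reported scheme: an 11x11/stride-4 first layer, then 5x5/stride-1
    convolutions, each followed by 5x5/stride-2 spatial max pooling."""
    k = [(11, 4), (5, 1), (5, 1), (5, 1)]
    return [
        LayerSpec(conv_kernel=ck, conv_stride=cs, pool_kernel=5, pool_stride=2, n_filters=f)
        for (ck, cs), f in zip(k, filters)
    ]


@dataclass(frozen=True)
class ENNConfig:
    layers: tuple[LayerSpec, ...] = field(default_factory=lambda: tuple(default_layers()))
    pyramid: PyramidSpec = field(default_factory=PyramidSpec)
    n_classes: int = 10
    scale_pool: str = "max"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if len(self.layers) != 4:
            raise ValueError("ENN uses exactly 4 conv/pool layers plus one FC layer")
        if self.scale_pool != "max":
            raise ValueError("only max scale pooling is supported")


@dataclass(frozen=True)
class CNNConfig:
    layers: tuple[LayerSpec, ...] = field(default_factory=lambda: tuple(default_layers()))
    input_resolution: float = 450.0 / 1.5**4  # px/deg of ENN channel index 4
    fc_input_px: int = 225
    n_classes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if len(self.layers) != 4:
            raise ValueError("CNN uses exactly 4 conv/pool layers plus one FC layer")
        if self.input_resolution <= 0 or self.fc_input_px < 1:
            raise ValueError("invalid input geometry")


def cnn_config_from_enn(
    enn_cfg: ENNConfig,
    calib: FieldCalibration,
    train_field_span: float | None = None,
    mid_channel: int = 4,
) -> CNNConfig:
    """Single-channel control matched to the ENN: same layer parameters,
    input resolution equal to that of ENN scale channel ``mid_channel``."""
    res = channel_resolution(enn_cfg.pyramid, mid_channel, calib.pixels_per_degree)
    span = calib.field_span if train_field_span is None else train_field_span
    fc_px = max(1, int(np.floor(span * res + 0.5)))
    return CNNConfig(
        layers=enn_cfg.layers,
        input_resolution=res,
        fc_input_px=fc_px,
        n_classes=enn_cfg.n_classes,
        seed=enn_cfg.seed,
    )


class _Trunk:
    """The shared 4-layer conv/ReLU/pool stack."""

    def __init__(self, layers: tuple[LayerSpec, ...], rng: np.random.Generator):
        self.blocks = []
        c_in = 1
        for ls in layers:
            self.blocks.append(
                Conv2d(c_in, ls.n_filters, ls.conv_kernel, ls.conv_stride,
                       pad=ls.conv_kernel // 2, rng=rng)
            )
            self.blocks.append(ReLU())
            self.blocks.append(MaxPool2d(ls.pool_kernel, ls.pool_stride))
            c_in = ls.n_filters

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for blk in self.blocks:
            x = blk.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for blk in reversed(self.blocks):
            dout = blk.backward(dout)
        return dout

    def params(self):
        out = []
        for blk in self.blocks:
            out.extend(blk.params())
        return out

    def out_dim(self, side: int) -> int:
        z = np.zeros((1, 1, side, side), dtype=np.float32)
        return int(self.forward(z).size)


class ENN:
    """Shared-weight multi-scale network with element-wise max scale pooling."""

    def __init__(self, config: ENNConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.trunk = _Trunk(config.layers, rng)
        self.feature_dim = self.trunk.out_dim(config.pyramid.common_grid)
        self.fc = Linear(self.feature_dim, config.n_classes, rng)
        self._cache = None

    def params(self):
        return self.trunk.params() + self.fc.params()

    def forward(
        self, x: np.ndarray, train: bool = False
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """``x``: (B, n_channels, grid, grid) preprocessed pyramid batch.

        Returns (bank, pooled, scores): the per-channel feature bank
        (B, n_channels, D), the scale-pooled feature (B, D), and class
        scores (B, n_classes).
        """
        B, nch, g1, g2 = x.shape
        grid = self.config.pyramid.common_grid
        if nch != self.config.pyramid.n_channels or g1 != grid or g2 != grid:
            raise ValueError(
                f"input {x.shape} does not match pyramid "
                f"({self.config.pyramid.n_channels} x {grid} x {grid})"
            )
        feats = self.trunk.forward(x.reshape(B * nch, 1, g1, g2), train=train)
        bank = feats.reshape(B, nch, -1)
        arg = bank.argmax(axis=1)  # (B, D)
        pooled = np.take_along_axis(bank, arg[:, None, :], axis=1)[:, 0, :]
        scores = self.fc.forward(pooled, train=train)
        if train:
            self._cache = (arg, bank.shape, feats.shape)
        return bank, pooled, scores

    def backward(self, dscores: np.ndarray) -> None:
        arg, bank_shape, feat_shape = self._cache
        dpooled = self.fc.backward(dscores)
        dbank = np.zeros(bank_shape, dtype=np.float32)
        np.put_along_axis(dbank, arg[:, None, :], dpooled[:, None, :], axis=1)
        self.trunk.backward(dbank.reshape(feat_shape))

    def features(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        bank, pooled, _ = self.forward(x, train=False)
        return bank, pooled


class CNN:
    """Single-resolution control: identical layer parameters, one channel,
    no scale pooling."""

    def __init__(self, config: CNNConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.trunk = _Trunk(config.layers, rng)
        self.feature_dim = self.trunk.out_dim(config.fc_input_px)
        self.fc = Linear(self.feature_dim, config.n_classes, rng)
        self._cache = None

    def params(self):
        return self.trunk.params() + self.fc.params()

    def forward(self, x: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """``x``: (B, 1, H, W).  Returns (features, scores); scores require
        H = W = config.fc_input_px."""
        B = x.shape[0]
        feats = self.trunk.forward(x, train=train).reshape(B, -1)
        if feats.shape[1] != self.feature_dim:
            raise ValueError(
                f"feature dim {feats.shape[1]} != FC input {self.feature_dim}; "
                f"classification requires {self.config.fc_input_px}-px inputs"
            )
        scores = self.fc.forward(feats, train=train)
        if train:
            self._cache = feats.shape
        return feats, scores

    def backward(self, dscores: np.ndarray) -> None:
        dfeats = self.fc.backward(dscores)
        pooled_shape = self.trunk.blocks[-1]._cache  # noqa: SLF001 - shape via cache
        B = dfeats.shape[0]
        # recover the spatial shape of the last pool output
        arg, _, (ho, wo), _ = pooled_shape
        c = arg.shape[1]
        self.trunk.backward(dfeats.reshape(B, c, ho, wo))

    def features(self, x: np.ndarray) -> np.ndarray:
        """Conv+pool features with the FC layer removed; any input size."""
        B = x.shape[0]
        return self.trunk.forward(x, train=False).reshape(B, -1)


# ---------------------------------------------------------------------------
# input preprocessing


def pyramid_input(pyr: CropPyramid) -> np.ndarray:
    """Network input for one pyramid: stimulus-positive on a zero background."""
    return np.abs(pyr.channels - pyr.background).astype(np.float32)


def cnn_input(image: VisualFieldImage, resolution: float) -> np.ndarray:
    """Full-field image downsampled to ``resolution`` px/deg, stimulus-positive."""
    ppd = image.calibration.pixels_per_degree
    side = max(1, int(np.floor(image.pixels.shape[0] * resolution / ppd + 0.5)))
    small = resize_raster(image.pixels, (side, side))
    return np.abs(small - image.background).astype(np.float32)[None, :, :]


class ENNExtractor:
    """Renders an image into pyramid features (FeatureBank, PooledFeature)."""

    def __init__(self, model: ENN, pyramid_spec: PyramidSpec | None = None):
        self.model = model
        self.pyramid_spec = pyramid_spec or model.config.pyramid

    def bank_and_pooled(self, image: VisualFieldImage) -> tuple[np.ndarray, np.ndarray]:
        pyr = sample_pyramid(image, self.pyramid_spec)
        x = pyramid_input(pyr)[None]
        bank, pooled = self.model.features(x)
        return bank[0], pooled[0]


class CNNExtractor:
    """Single-channel features; the "bank" degenerates to one channel, so the
    asymmetric metric reduces to the symmetric one."""

    def __init__(self, model: CNN, input_resolution: float | None = None):
        self.model = model
        self.input_resolution = input_resolution or model.config.input_resolution

    def bank_and_pooled(self, image: VisualFieldImage) -> tuple[np.ndarray, np.ndarray]:
        x = cnn_input(image, self.input_resolution)[None]
        feats = self.model.features(x)
        return feats, feats[0]


# ---------------------------------------------------------------------------
# training


class TrainingError(RuntimeError):
    """Raised when training diverges (non-finite loss)."""


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 4
    lr: float = 1e-3
    batch_size: int = 32
    val_fraction: float = 0.1
    seed: int = 0


def _model_scores(model, xb, train):
    out = model.forward(xb, train=train)
    return out[-1]  # scores are always last


def _accuracy(model, X, y, batch_size: int = 64) -> float:
    correct = 0
    for i in range(0, len(y), batch_size):
        xb = _as_float(X[i : i + batch_size])
        scores = _model_scores(model, xb, train=False)
        correct += int((scores.argmax(axis=1) == y[i : i + batch_size]).sum())
    return correct / max(1, len(y))


def _as_float(x: np.ndarray) -> np.ndarray:
    if x.dtype == np.uint8:
        return x.astype(np.float32) / 255.0
    return x.astype(np.float32, copy=False)


def train(
    model, X: np.ndarray, y: np.ndarray, config: TrainConfig = TrainConfig()
) -> list[dict]:
    """Minimize softmax cross-entropy with Adam; returns a per-epoch log of
    mean loss and held-out accuracy.  ``X`` may be uint8 (scaled by 255) to
    save memory; inputs are ENN pyramid batches or CNN image batches.

    Zero epochs returns immediately with the randomly initialized weights.
    """
    y = np.asarray(y, dtype=np.int64)
    rng = np.random.default_rng(config.seed)
    n = len(y)
    perm = rng.permutation(n)
    n_val = int(np.floor(n * config.val_fraction))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    opt = Adam(model.params(), lr=config.lr)
    log: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            xb = _as_float(X[idx])
            yb = y[idx]
            opt.zero_grad()
            scores = _model_scores(model, xb, train=True)
            loss, dscores = softmax_cross_entropy(scores, yb)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            model.backward(dscores)
            opt.step()
            losses.append(loss)
        entry = {
            "epoch": epoch,
            "loss": float(np.mean(losses)) if losses else float("nan"),
            "val_accuracy": _accuracy(model, X[val_idx], y[val_idx]) if n_val else float("nan"),
        }
        log.append(entry)
    return log


# ---------------------------------------------------------------------------
# checkpoints


def _config_dict(model) -> dict:
    d = asdict(model.config)
    d["model_kind"] = type(model).__name__
    return d


def config_hash(model_or_dict) -> str:
    d = model_or_dict if isinstance(model_or_dict, dict) else _config_dict(model_or_dict)
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def save_weights(model, path: str | Path) -> None:
    arrays = {f"p{i}": p for i, (p, _) in enumerate(model.params())}
    cfg = _config_dict(model)
    np.savez(
        path,
        __config__=np.frombuffer(json.dumps(cfg, sort_keys=True).encode(), dtype=np.uint8),
        __hash__=np.frombuffer(config_hash(cfg).encode(), dtype=np.uint8),
        **arrays,
    )


def load_weights(model, path: str | Path) -> None:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        if config_hash(cfg) != config_hash(model):
            raise ValueError("checkpoint config hash does not match model config")
        for i, (p, _) in enumerate(model.params()):
            p[...] = data[f"p{i}"]
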