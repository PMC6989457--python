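"""Config-driven reproduction of the scale- and translation-invariance
simulations at desk scale.

The default profile is deliberately small (reduced pixels-per-degree,
filter counts and training set) so that a full train-and-evaluate cycle
runs in minutes on one CPU; the geometry (10 scale channels, growth factor
1.5, 0.5-degree foveal crop, ~19-degree field) matches the full-scale model
exactly, only the pixel sampling is coarser.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import networks as nets
from .oneshot import (
    ConditionSpec,
    InvarianceWindow,
    build_window,
    correlation_vs_eccentricity,
    run_condition,
)
from .pyramid import PyramidSpec, sample_pyramid
from .stimuli import (
    AugmentationPolicy,
    FieldCalibration,
    GlyphSet,
    LabeledImages,
    iter_training_set,
    make_novel_pairs,
    make_training_classes,
)

__all__ = [
    "ExperimentConfig",
    "TrainedModels",
    "config_hash",
    "build_models",
    "train_models",
    "run_scale_experiment",
    "run_translation_experiment",
    "plot_window",
]


@dataclass(frozen=True)
class ExperimentConfig:
    # field geometry (desk-scale default: 200 px/deg instead of 450)
    pixels_per_degree: float = 200.0
    n_channels: int = 10
    growth_factor: float = 1.5
    smallest_span: int = 100
    common_grid: int = 100
    # model
    filters: tuple[int, int, int, int] = (16, 16, 32, 128)
    n_classes: int = 10
    # training data (procedural digit-like glyph classes)
    items_per_class: int = 20
    samples_per_item: int = 10
    train_size_range: tuple[float, float] = (20.0, 120.0)
    train_ecc_range: tuple[float, float] = (-2.5, 2.5)
    train_field_span: float = 8.0
    # optimization
    epochs: int = 6
    lr: float = 1e-3
    batch_size: int = 32
    val_fraction: float = 0.1
    # one-shot test set (novel glyph pairs)
    n_pairs: int = 27
    pair_seed_offset: int = 10_000
    # condition grids (sizes arcmin, eccentricities deg)
    scale_conditions: tuple[tuple[float, float], ...] = (
        (30.0, 30.0), (30.0, 120.0), (120.0, 30.0), (30.0, 300.0), (300.0, 30.0),
    )
    translation_grid: tuple[tuple[float, tuple[float, ...]], ...] = (
        (30.0, (1.0, 2.0, 3.0)),
        (60.0, (2.0, 2.5)),
        (120.0, (2.0, 4.0, 5.0, 7.0)),
    )
    regimes: tuple[str, ...] = ("central", "peripheral", "opposite")
    enn_metric: str = "asymmetric"
    window_threshold: float = 0.85
    seed: int = 0

    # ------------------------------------------------------------------
    @property
    def pyramid(self) -> PyramidSpec:
        return PyramidSpec(self.n_channels, self.growth_factor,
                           self.smallest_span, self.common_grid)

    @property
    def field_span(self) -> float:
        from .pyramid import crop_spans

        return crop_spans(self.pyramid)[-1] / self.pixels_per_degree

    @property
    def eval_calibration(self) -> FieldCalibration:
        return FieldCalibration(self.pixels_per_degree, self.field_span)

    @property
    def train_calibration(self) -> FieldCalibration:
        return FieldCalibration(self.pixels_per_degree, self.train_field_span)

    @property
    def cnn_eval_calibration(self) -> FieldCalibration:
        """Full-span field rendered directly at the CNN's input resolution
        (identical geometry, cheaper rendering than downsampling)."""
        from .pyramid import channel_resolution

        res = channel_resolution(self.pyramid, 4, self.pixels_per_degree)
        return FieldCalibration(res, self.field_span)

    def with_seed(self, seed: int) -> "ExperimentConfig":
        return replace(self, seed=seed)

    # ------------------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_jsonable(asdict(self)), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["filters"] = tuple(raw["filters"])
        raw["train_size_range"] = tuple(raw["train_size_range"])
        raw["train_ecc_range"] = tuple(raw["train_ecc_range"])
        raw["scale_conditions"] = tuple(tuple(c) for c in raw["scale_conditions"])
        raw["translation_grid"] = tuple(
            (s, tuple(eccs)) for s, eccs in raw["translation_grid"]
        )
        raw["regimes"] = tuple(raw["regimes"])
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_hash(cfg: ExperimentConfig) -> str:
    return hashlib.sha256(
        json.dumps(_jsonable(asdict(cfg)), sort_keys=True).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# dataset assembly


def pyramid_dataset(images: LabeledImages, spec: PyramidSpec) -> np.ndarray:
    """Precompute pyramids for a labeled image set as a uint8 tensor
    (N, n_channels, grid, grid), stimulus-positive, scaled by 255."""
    out = np.empty(
        (len(images), spec.n_channels, spec.common_grid, spec.common_grid), dtype=np.uint8
    )
    for i, img in enumerate(images.images):
        x = nets.pyramid_input(sample_pyramid(img, spec))
        out[i] = (np.clip(x, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    return out


def cnn_dataset(images: LabeledImages, resolution: float) -> np.ndarray:
    """Precompute CNN inputs as a uint8 tensor (N, 1, H, W)."""
    first = nets.cnn_input(images.images[0], resolution)
    out = np.empty((len(images),) + first.shape, dtype=np.uint8)
    for i, img in enumerate(images.images):
        x = nets.cnn_input(img, resolution)
        out[i] = (np.clip(x, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    return out


@dataclass
class TrainedModels:
    enn: nets.ENN
    cnn: nets.CNN
    enn_log: list[dict] = field(default_factory=list)
    cnn_log: list[dict] = field(default_factory=list)
    seed: int = 0


def make_test_pairs(cfg: ExperimentConfig) -> GlyphSet:
    return make_novel_pairs(cfg.n_pairs, cfg.seed + cfg.pair_seed_offset)


def build_models(cfg: ExperimentConfig) -> TrainedModels:
    """Instantiate matched ENN and CNN (randomly initialized, untrained)."""
    enn_cfg = nets.ENNConfig(
        layers=tuple(nets.default_layers(cfg.filters)),
        pyramid=cfg.pyramid,
        n_classes=cfg.n_classes,
        seed=cfg.seed,
    )
    cnn_cfg = nets.cnn_config_from_enn(
        enn_cfg, cfg.train_calibration, train_field_span=cfg.train_field_span
    )
    return TrainedModels(nets.ENN(enn_cfg), nets.CNN(cnn_cfg), [], [], cfg.seed)


def train_models(cfg: ExperimentConfig, verbose: bool = False) -> TrainedModels:
    """Train ENN and CNN with identical data and budgets on augmented
    digit-like glyph classes."""
    classes = make_training_classes(cfg.n_classes, cfg.items_per_class, cfg.seed)
    policy = AugmentationPolicy(
        cfg.train_size_range, cfg.train_ecc_range, cfg.samples_per_item, cfg.seed
    )

    models = build_models(cfg)
    enn, cnn = models.enn, models.cnn
    cnn_cfg = cnn.config
    tc = nets.TrainConfig(cfg.epochs, cfg.lr, cfg.batch_size, cfg.val_fraction, cfg.seed)

    # stream the renders: full-field rasters are large, the uint8 network
    # inputs are small, so build both model datasets in one pass
    n = cfg.n_classes * cfg.items_per_class * cfg.samples_per_item
    spec = cfg.pyramid
    X_enn = np.empty((n, spec.n_channels, spec.common_grid, spec.common_grid),
                     dtype=np.uint8)
    X_cnn = None
    labels = np.empty(n, dtype=np.int64)
    for i, (img, label, _) in enumerate(
        iter_training_set(classes, policy, cfg.train_calibration)
    ):
        xp = nets.pyramid_input(sample_pyramid(img, spec))
        X_enn[i] = (np.clip(xp, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
        xc = nets.cnn_input(img, cnn_cfg.input_resolution)
        if X_cnn is None:
            X_cnn = np.empty((n,) + xc.shape, dtype=np.uint8)
        X_cnn[i] = (np.clip(xc, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
        labels[i] = label

    enn_log = nets.train(enn, X_enn, labels, tc)
    del X_enn
    cnn_log = nets.train(cnn, X_cnn, labels, tc)
    del X_cnn
    if verbose:
        print(f"ENN log: {enn_log}\nCNN log: {cnn_log}")
    return TrainedModels(enn, cnn, enn_log, cnn_log, cfg.seed)


# ---------------------------------------------------------------------------
# experiments


def _result_row(cfg: ExperimentConfig, model_name: str, res) -> dict:
    s = res.spec
    return {
        "model": model_name,
        "regime": s.regime,
        "metric": s.metric,
        "target_size_arcmin": s.target_size,
        "test_size_arcmin": s.test_size,
        "target_ecc_deg": s.target_ecc,
        "test_ecc_deg": s.test_ecc,
        "accuracy": res.accuracy,
        "threshold": res.threshold,
        "d_prime": res.d_prime,
        "hit_rate": res.hit_rate,
        "fa_rate": res.fa_rate,
        "n_trials": res.n_trials,
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
    }


def run_scale_experiment(
    cfg: ExperimentConfig, trained: TrainedModels | None = None
) -> pd.DataFrame:
    """Same/different accuracy for target/test size combinations at fixation,
    for ENN and CNN, on novel glyph pairs (scale-invariance simulation).

    Scale conditions use the symmetric (scale-pooled) metric for both models.
    """
    trained = trained or train_models(cfg)
    pairs = make_test_pairs(cfg)
    extractors = {
        "ENN": (nets.ENNExtractor(trained.enn, cfg.pyramid), cfg.eval_calibration),
        "CNN": (nets.CNNExtractor(trained.cnn), cfg.cnn_eval_calibration),
    }
    rows = []
    for model_name, (extractor, calib) in extractors.items():
        for t_size, s_size in cfg.scale_conditions:
            spec = ConditionSpec(t_size, s_size, 0.0, 0.0, "central", "symmetric")
            res = run_condition(spec, pairs, extractor, calib)
            rows.append(_result_row(cfg, model_name, res))
    return pd.DataFrame(rows)


def _regime_eccs(regime: str, ecc: float) -> tuple[float, float]:
    return {
        "central": (0.0, ecc),
        "peripheral": (ecc, 0.0),
        "same": (ecc, ecc),
        "opposite": (ecc, -ecc),
    }[regime]


def run_translation_experiment(
    cfg: ExperimentConfig,
    trained: TrainedModels | None = None,
    models: tuple[str, ...] = ("ENN", "CNN"),
) -> dict:
    """Invariance windows over the (size, eccentricity) grid for the
    configured regimes, plus the raw correlation-vs-eccentricity table.

    The ENN uses the configured metric (default asymmetric channel
    selection); the CNN, having a single scale channel, uses the symmetric
    metric.  Window nodes are keyed by the eccentricity D of the displaced
    presentation (test for central, target for peripheral/opposite).
    """
    trained = trained or train_models(cfg)
    pairs = make_test_pairs(cfg)
    extractors = {
        "ENN": (nets.ENNExtractor(trained.enn, cfg.pyramid), cfg.enn_metric,
                cfg.eval_calibration),
        "CNN": (nets.CNNExtractor(trained.cnn), "symmetric", cfg.cnn_eval_calibration),
    }
    rows = []
    windows: dict[tuple[str, str], InvarianceWindow] = {}
    for model_name in models:
        extractor, metric, calib = extractors[model_name]
        for regime in cfg.regimes:
            nodes = {}
            for size, eccs in cfg.translation_grid:
                for ecc in (0.0, *eccs):
                    t_ecc, s_ecc = _regime_eccs(regime, ecc)
                    spec = ConditionSpec(size, size, t_ecc, s_ecc, regime, metric)
                    res = run_condition(spec, pairs, extractor, calib)
                    rows.append(_result_row(cfg, model_name, res))
                    nodes[(size, ecc)] = res
            windows[(model_name, regime)] = build_window(nodes, regime)

    # raw same-glyph correlation against eccentricity (central presentation
    # as reference), per tested size
    corr_frames = []
    for model_name in models:
        extractor, metric, calib = extractors[model_name]
        for size, eccs in cfg.translation_grid:
            df = correlation_vs_eccentricity(
                pairs, size, [0.0, *eccs], extractor, calib, metric
            )
            df.insert(0, "model", model_name)
            corr_frames.append(df)
    corr = pd.concat(corr_frames, ignore_index=True)
    corr["seed"] = cfg.seed
    corr["config_hash"] = config_hash(cfg)

    return {
        "results": pd.DataFrame(rows),
        "windows": windows,
        "correlations": corr,
        "trained": trained,
    }


def plot_window(window: InvarianceWindow, path: str | Path, title: str = "") -> None:
    """Interpolated accuracy heatmap with measured nodes marked as circles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sizes = sorted({s for s, _ in window.grid})
    eccs = sorted({e for _, e in window.grid})
    sg = np.linspace(min(sizes), max(sizes), 80)
    eg = np.linspace(min(eccs), max(eccs), 80)
    S, E = np.meshgrid(sg, eg, indexing="ij")
    Z = window.surface(S, E)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.pcolormesh(E, S, Z, vmin=0.5, vmax=1.0, shading="auto", cmap="viridis")
    ax.scatter([e for _, e in window.grid], [s for s, _ in window.grid],
               s=25, facecolors="none", edgecolors="k")
    ax.set_xlabel("eccentricity (deg)")
    ax.set_ylabel("letter size (arcmin)")
    ax.set_title(title or f"{window.regime} window")
    fig.colorbar(im, ax=ax, label="accuracy")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
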