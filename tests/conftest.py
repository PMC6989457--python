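import numpy as np
import pytest

from eccnet import (
    ENN,
    CNN,
    CNNConfig,
    ENNConfig,
    FieldCalibration,
    PyramidSpec,
    default_layers,
    make_novel_pairs,
)


@pytest.fixture(scope="session")
def calib450() -> FieldCalibration:
    """Full-scale calibration (450 px/deg) on a reduced 2-deg field."""
    return FieldCalibration(450.0, 2.0)


@pytest.fixture(scope="session")
def small_calib() -> FieldCalibration:
    """Coarse desk calibration: 60 px/deg over 8 deg (480 px field)."""
    return FieldCalibration(60.0, 8.0)


@pytest.fixture(scope="session")
def tiny_pyramid() -> PyramidSpec:
    """4-channel pyramid on a 30-px grid, matched to ``small_calib``."""
    return PyramidSpec(n_channels=4, growth_factor=1.5, smallest_span=30, common_grid=30)


@pytest.fixture(scope="session")
def pairs5():
    return make_novel_pairs(5, seed=7)


@pytest.fixture(scope="session")
def tiny_enn(tiny_pyramid) -> ENN:
    cfg = ENNConfig(
        layers=tuple(default_layers((8, 8, 16, 16))),
        pyramid=tiny_pyramid,
        n_classes=3,
        seed=0,
    )
    return ENN(cfg)


@pytest.fixture(scope="session")
def tiny_cnn() -> CNN:
    cfg = CNNConfig(
        layers=tuple(default_layers((4, 4, 8, 8))),
        input_resolution=12.0,
        fc_input_px=96,
        n_classes=3,
        seed=0,
    )
    return CNN(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
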