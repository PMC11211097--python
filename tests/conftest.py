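import numpy as np
import pytest

from fociquant import (
    DEFAULT_MAXIMA,
    DEFAULT_THRESHOLDS,
    CompartmentMap,
    SceneParams,
    ThresholdConfig,
    classify_compartments,
    generate_scene,
)


@pytest.fixture(scope="session")
def default_scene():
    """One default-parameter synthetic scene with its ground truth."""
    return generate_scene(SceneParams(seed=42))


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free scene: segmentation should be pixel-exact on it."""
    return generate_scene(SceneParams(seed=7, noise_sd=0.0))


@pytest.fixture
def worked_example_map():
    """3x3 scene used across modules: center pixel is the nucleus (green
    100), corners are cytosol (50 > threshold 30), edges background (10)."""
    green = np.array(
        [[50, 10, 50],
         [10, 100, 10],
         [50, 10, 50]], dtype=float
    )
    labels = np.zeros((3, 3), dtype=np.int32)
    labels[1, 1] = 1
    config = ThresholdConfig(dapi_threshold=100, background_threshold=30,
                             min_nucleus_area=0)
    return green, classify_compartments(green, labels, config)


def make_map(labels: np.ndarray, green: np.ndarray, background_threshold=0.0) -> CompartmentMap:
    """CompartmentMap from explicit nucleus labels (testing helper)."""
    cfg = ThresholdConfig(dapi_threshold=0, background_threshold=background_threshold,
                          min_nucleus_area=0)
    return classify_compartments(green, labels, cfg)
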