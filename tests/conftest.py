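import numpy as np
import pytest

from reddmap import SceneConfig, default_lake_scheme, generate_scene


@pytest.fixture(scope="session")
def scheme():
    return default_lake_scheme()


@pytest.fixture(scope="session")
def small_scene():
    """A compact lake scene for fast end-to-end tests."""
    return generate_scene(SceneConfig(
        height=192, width=192, rng_seed=11,
        redd_blob_count=10, rock_blob_count=14,
        train_pixels_per_class=300, truth_pixels_per_class=300))


@pytest.fixture(scope="session")
def survey_scene():
    """A full-size scene at the default survey design (512x512, ~975
    training and ~1000 ground-truth pixels per class)."""
    return generate_scene(SceneConfig(rng_seed=42))


def random_class_map_labels(rng, shape, n_classes, p_zero=0.0):
    """Seeded random label raster over 0..n_classes."""
    labels = rng.integers(1, n_classes + 1, size=shape)
    if p_zero:
        labels[rng.random(shape) < p_zero] = 0
    return labels.astype(np.int64)
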