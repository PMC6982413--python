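import numpy as np
import pytest

from chorodig import (SegmentationParams, SyntheticMapSpec, deer_density_legend,
                      make_synthetic_map, multiresolution_segment)


@pytest.fixture(scope="session")
def legend():
    return deer_density_legend()


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down synthetic scene used by most tests (fast to segment)."""
    return SyntheticMapSpec(n_units=8, width=150, height=100, seed=11)


@pytest.fixture(scope="session")
def small_scene(small_spec):
    img, gt, zones = make_synthetic_map(small_spec)
    return img, gt, zones


@pytest.fixture(scope="session")
def small_segmentation(small_scene):
    img, _, _ = small_scene
    return multiresolution_segment(img, SegmentationParams(scale=10.0))


@pytest.fixture(scope="session")
def clean_spec():
    """Undegraded scene: exact palette colors, no blur or noise."""
    return SyntheticMapSpec(n_units=8, width=150, height=100, seed=5,
                            blur_sigma=0.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def clean_scene(clean_spec):
    img, gt, zones = make_synthetic_map(clean_spec)
    return img, gt, zones


def solid_image(h, w, color):
    return np.tile(np.asarray(color, np.uint8), (h, w, 1))
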