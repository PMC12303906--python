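import math

import numpy as np
import pytest

from plaquenet.phantom import PhantomConfig, generate_dataset, write_dataset
from plaquenet.pipeline import SplitSpec, split_manifest


def small_phantom_config(**overrides) -> PhantomConfig:
    """64x64 phantom settings small enough for fast tests."""
    kwargs = dict(
        image_height_px=64,
        image_width_px=64,
        pixel_spacing_mm=0.12,
        plaque_long_axis_range_mm=(1.0, 2.6),
        plaque_aspect_ratio_range=(0.45, 0.85),
        plaque_contrast=0.25,
        speckle_looks=4.0,
        edge_blur_sigma_px=1.0,
        shadow_probability=0.25,
        seed=7,
    )
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


def clean_phantom_config(**overrides) -> PhantomConfig:
    """Noise-free variant: no speckle, no blur, no shadow."""
    return small_phantom_config(
        speckle_looks=math.inf, edge_blur_sigma_px=0.0, shadow_probability=0.0,
        **overrides)


@pytest.fixture(scope="session")
def clean_samples():
    return generate_dataset(clean_phantom_config(seed=3), 30)


@pytest.fixture(scope="session")
def noisy_samples():
    return generate_dataset(small_phantom_config(seed=11), 30)


@pytest.fixture(scope="session")
def dataset287(tmp_path_factory):
    """287 tiny phantoms written to disk and split 7:1:2, as in the
    clinical protocol's sample-count layout."""
    cfg = PhantomConfig(
        image_height_px=32, image_width_px=32, pixel_spacing_mm=0.1,
        plaque_long_axis_range_mm=(0.6, 1.2),
        plaque_aspect_ratio_range=(0.5, 0.9),
        speckle_looks=4.0, edge_blur_sigma_px=0.8, shadow_probability=0.2,
        seed=287)
    root = tmp_path_factory.mktemp("dataset287")
    man = write_dataset(generate_dataset(cfg, 287), root)
    return split_manifest(man, SplitSpec(ratios=(7, 1, 2), seed=5))
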