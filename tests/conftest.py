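"""Shared fixtures: small phantom scenes reused across test modules."""

import numpy as np
import pytest

from roottrack import ExperimentConfig, SceneConfig, generate_scene

#: Absolute segmentation threshold suited to the default phantom intensity
#: scale (background 10, blob peak 100): sits far above the noise floor and
#: well below the blob cores on every frame, including event-free ones.
PHANTOM_THRESHOLD = 30.0


def small_scene_config(**overrides) -> SceneConfig:
    defaults = dict(n_frames=6, n_events=4, drift_voxels_per_frame=(0, 5, 0))
    defaults.update(overrides)
    return SceneConfig(**defaults)


@pytest.fixture(scope="session")
def small_scene():
    """A 6-frame phantom with 4 events and 5-voxel lateral drift."""
    return generate_scene(small_scene_config(), seed=3)


@pytest.fixture(scope="session")
def phantom_config() -> ExperimentConfig:
    return ExperimentConfig(threshold=PHANTOM_THRESHOLD)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
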