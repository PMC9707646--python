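import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from foci3d import DEFAULT_GEOMETRY, RunConfig, SceneParams, generate_scene, run_pipeline

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def geometry():
    """The spinning-disk acquisition geometry (0.0662 x 0.0662 x 0.5 um)."""
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def small_scene_params():
    """A one-cell field small enough for fast unit tests."""
    return SceneParams(image_shape=(31, 256, 256), n_cells=1, seed=5)


@pytest.fixture(scope="session")
def small_scene(small_scene_params):
    """Rendered one-cell scene plus ground truth (shared, treat as read-only)."""
    return generate_scene(small_scene_params)


@pytest.fixture(scope="session")
def small_result(small_scene):
    """Pipeline output on the shared one-cell scene."""
    bundle, _ = small_scene
    return run_pipeline(bundle, RunConfig())


def make_scene(**overrides):
    params = SceneParams(**{"image_shape": (31, 256, 256), "n_cells": 1, "seed": 5, **overrides})
    return generate_scene(params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
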