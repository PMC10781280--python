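"""Shared fixtures: small synthetic scenes and captures."""

import numpy as np
import pytest

from larvadet.synthetic import SceneSpec, generate_capture


@pytest.fixture(scope="session")
def small_scene() -> SceneSpec:
    """A 400-px scene with a clearly visible larva, GRE-dominant."""
    return SceneSpec(
        image_side=400,
        larva_length=70.0,
        larva_width=5.0,
        larva_orientation=35.0,
        larva_curvature=0.1,
        larva_center=(210.0, 180.0),
        noise_sd=5.0,
    )


@pytest.fixture(scope="session")
def small_capture(small_scene):
    return generate_capture(small_scene, seed=7)


@pytest.fixture(scope="session")
def blank_scene() -> SceneSpec:
    return SceneSpec(image_side=400, larva_present=False, noise_sd=5.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
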