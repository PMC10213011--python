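"""Shared fixtures: small synthetic transects sized for fast tests."""

from __future__ import annotations

import numpy as np
import pytest

from benthic_ready.synthetic import SceneParams, generate_scene, generate_transect

#: Small frame geometry used by most tests: 240x360 px at base scale
#: 15 px/cm at 1 m, so 5-15 px/cm over the 1-3 m altitude range.
SMALL = dict(width_px=360, height_px=240, base_scale_px_per_cm_at_1m=15.0)


@pytest.fixture(scope="session")
def small_params() -> SceneParams:
    return SceneParams(seed=11, **SMALL)


@pytest.fixture(scope="session")
def small_scene(small_params):
    return generate_scene(small_params)


@pytest.fixture(scope="session")
def small_transect():
    """12 small frames over a 1-3 m altitude sweep (one light-cone batch)."""
    return generate_transect(12, seed=23, params=SceneParams(**SMALL))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
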