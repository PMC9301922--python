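"""Shared fixtures: one small synthetic scene reused across unit tests."""

import numpy as np
import pandas as pd
import pytest

from no2map import GridSpec, SceneConfig, simulate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A 40x40-cell, 8-day scene; cheap enough for many tests to share."""
    cfg = SceneConfig(
        spec=GridSpec(30.0, 30.4, 110.0, 110.4, 0.01),
        n_days=8,
        n_stations=60,
        n_hotspots=6,
        seed=11,
    )
    return simulate_scene(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
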