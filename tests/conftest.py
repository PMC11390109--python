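"""Shared fixtures: synthetic worlds at two scales, built once per session.

All test data are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from flyscape.raster import RasterGrid
from flyscape.synthetic import SimulationConfig, generate_dem, simulate_population
from flyscape.terrain import compute_terrain_layers


def small_config(**kw) -> SimulationConfig:
    """A reduced world for fast end-to-end tests: 3 birds, 12 weeks,
    120 km extent, otherwise the default study conditions."""
    base = dict(
        seed=11,
        n_individuals=3,
        post_emigration_weeks=12,
        extent_m=120_000.0,
        n_ridges=5,
        noncommuting_mean_bout_h=20.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_world():
    cfg = small_config()
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def default_landscape():
    """The fixed study-scale landscape (250 km, 100 m cells) shared by the
    recovery replicates."""
    cfg = SimulationConfig(seed=1)
    dem = generate_dem(cfg)
    terrain = compute_terrain_layers(dem)
    return dem, terrain


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_raster(rng):
    """A 20x20 25 m raster of rough random terrain."""
    return RasterGrid(0.0, 500.0, 25.0, rng.normal(1000.0, 50.0, (20, 20)))
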