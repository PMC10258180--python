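import numpy as np
import pytest

from aumex.raster import Grid, Raster


@pytest.fixture
def grid():
    """Small 16x16 grid, 100 m cells, origin at (0, 1600)."""
    return Grid(n_rows=16, n_cols=16, cell_size=100.0, origin_x=0.0, origin_y=1600.0)


@pytest.fixture
def flat_dem(grid):
    return Raster(grid, np.full(grid.shape, 50.0))


@pytest.fixture
def inclined_dem(grid):
    """Plane dipping east: z decreases with x."""
    xx, _ = grid.cell_centers()
    return Raster(grid, 100.0 - xx * 0.01)


@pytest.fixture(scope="session")
def small_world():
    """A cheap replicate world with layers and model, shared across tests."""
    from aumex.experiment import replicate_config
    from aumex.pipeline import build_layers, build_model, simulate_world

    cfg = replicate_config(11, n_samples=1200)
    cfg.validation.n_subset = 400
    world = simulate_world(cfg)
    layers = build_layers(cfg, world)
    model = build_model(cfg, world, layers)
    return cfg, world, layers, model
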