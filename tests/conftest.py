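import numpy as np
import pytest

from mesohab.grid import ModelGrid
from mesohab.pipeline import PipelineConfig, run_pipeline
from mesohab.synthetic import generate_grid

SMALL_SYNTH_GRID = {
    "nx": 10, "ny": 12, "shelf_width_cells": 3, "max_depth_m": 3000.0,
    "lat_range": (34.0, 40.5), "lon_range": (-123.6, -121.8),
}


@pytest.fixture(scope="session")
def small_grid() -> ModelGrid:
    """Idealised shelf grid small enough for fast column-level tests."""
    return generate_grid(**SMALL_SYNTH_GRID)


def uniform_grid(ny=2, nx=2, area=1.0, bottom=1000.0, lat=36.0):
    """Flat-bottomed all-water helper grid with equal cell areas."""
    shape = (ny, nx)
    return ModelGrid(
        lat=np.full(shape, lat),
        lon=np.linspace(-125.0, -124.0, nx)[None, :].repeat(ny, axis=0),
        bottom_depth=np.full(shape, bottom, dtype=float),
        land_mask=np.zeros(shape, dtype=bool),
        cell_area=np.full(shape, area, dtype=float),
    )


@pytest.fixture(scope="session")
def century_run(tmp_path_factory):
    """Full-century default-ensemble pipeline run on the small grid.

    Shared by the tests that examine ensemble-level behaviour; the run is
    deterministic for the fixed seed.
    """
    cfg = PipelineConfig(synth_grid=dict(SMALL_SYNTH_GRID), seed=7)
    out = tmp_path_factory.mktemp("century_run")
    return cfg, run_pipeline(cfg, out), out
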