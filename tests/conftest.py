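import numpy as np
import pandas as pd
import pytest

from karststand.config import StandConfig
from karststand.synthetic import generate_scenario
from karststand.terrain import (
    build_quadrat_grid,
    classify_site_type,
    compute_terrain,
    set_elevations,
)


@pytest.fixture(scope="session")
def small_config() -> StandConfig:
    return StandConfig(
        plot_width=60.0,
        plot_height=40.0,
        n_stems=300,
        pattern="poisson",
        species_abundances=[0.5, 0.3, 0.2],
        rock_target_fraction=0.30,
        rock_blob_params=(8, 8.0),
        elevation_trend=(1293.0, 25.0, 200.0),
        elevation_noise_sd=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_scenario(small_config):
    return generate_scenario(small_config)


@pytest.fixture(scope="session")
def small_grid(small_scenario, small_config):
    grid = build_quadrat_grid(small_config.plot_width, small_config.plot_height, 10.0)
    set_elevations(grid, small_scenario.elevations)
    compute_terrain(grid)
    classify_site_type(grid, small_scenario.substrate)
    return grid


def make_stems(xy: np.ndarray, species=None, dbh=None, th=None, lifeform=None) -> pd.DataFrame:
    n = len(xy)
    return pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "x": xy[:, 0],
            "y": xy[:, 1],
            "species": species if species is not None else ["X"] * n,
            "dbh_cm": dbh if dbh is not None else np.full(n, 10.0),
            "th_m": th if th is not None else np.full(n, 8.0),
            "lifeform": lifeform if lifeform is not None else ["tree"] * n,
        }
    )
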