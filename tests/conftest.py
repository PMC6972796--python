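import numpy as np
import pandas as pd
import pytest

from ensemblesdm.grids import EnvStack, GridSpec
from ensemblesdm import synthetic
from ensemblesdm.occurrences import thin_to_pixels


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(n_rows=40, n_cols=40, lon_min=-30.0, lat_min=-10.0,
                    cell_size=0.5)


@pytest.fixture(scope="session")
def small_env(small_grid) -> EnvStack:
    return synthetic.generate_env_layers(
        small_grid, n_layers=4, smoothness=3.0, inter_layer_corr=0.9,
        collinear_pairs=[(0, 1)], land_fraction=0.15, seed=42)


@pytest.fixture(scope="session")
def strong_world():
    """Well-specified virtual species with a clear 2-driver signal."""
    grid = GridSpec(n_rows=80, n_cols=80, lon_min=-40.0, lat_min=-20.0,
                    cell_size=0.5)
    env = synthetic.generate_env_layers(
        grid, n_layers=6, smoothness=3.0, inter_layer_corr=0.9,
        collinear_pairs=[(0, 1)], land_fraction=0.2, seed=7)
    truth = synthetic.TrueModel(["env00", "env02"], -5.0,
                                {"env00": 1.8, "env02": -1.4})
    suit = synthetic.make_true_suitability(env, truth)
    records = synthetic.sample_survey(
        suit, grid, env.nodata_mask,
        effort_centers=[(-30.0, 0.0), (-15.0, -10.0)],
        n_records=6000, prevalence_target=0.015, kernel_sd_deg=6.0, seed=11)
    return env, truth, suit, records


@pytest.fixture(scope="session")
def strong_pixels(strong_world):
    env, truth, suit, records = strong_world
    return thin_to_pixels(records, env)


@pytest.fixture()
def toy_records() -> pd.DataFrame:
    return pd.DataFrame({
        "lon": [-20.0, -21.0, 0.0, -19.5, -20.2],
        "lat": [5.0, 6.0, 0.0, 5.5, 4.8],
        "detected": [1, 0, 1, 1, 0],
        "source": ["survey", "survey", "online", "online", "survey"],
        "imprecision_m": [np.nan, np.nan, 500.0, 10_001.0, np.nan],
    })
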