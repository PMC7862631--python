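import logging

import numpy as np
import pytest

import shrubipm as s
from shrubipm.synthetic_data import generate_climate_series
from shrubipm.vital_rates import build_design

logging.getLogger("shrubipm").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config():
    """Reduced study: 2 blocks x 10 plots, 6 censuses."""
    return s.default_config(n_plots_per_block=10, n_years=6, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    cfg = small_config
    rng = np.random.default_rng(cfg.seed)
    climate = generate_climate_series(cfg.n_years - 1, cfg.climate_ranges, rng,
                                      start_year=cfg.start_year)
    records, censuses = s.simulate_population(cfg, climate)
    return records, censuses, climate


@pytest.fixture(scope="session")
def small_design(small_dataset):
    records, censuses, climate = small_dataset
    return build_design(records, climate, censuses)


@pytest.fixture(scope="session")
def default_model_sets():
    """Generative-twin model sets for both species at packaged defaults."""
    cfg = s.default_config()
    return {sp: s.model_set_from_config(cfg, sp) for sp in ("HS", "LS")}


@pytest.fixture(scope="session")
def grid200():
    return s.build_grid(np.log(0.1), np.log(1500.0), 200)


@pytest.fixture(scope="session")
def climate_pool(default_model_sets, grid200):
    from shrubipm.scenarios import default_climate_pool

    return default_climate_pool(default_model_sets, seed=3, grid=grid200)


@pytest.fixture
def mean_climate():
    return s.ClimateYear(year=0, winter_min_temp=2.0, spring_rainfall=130.0,
                         summer_water_balance=-34.0)
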