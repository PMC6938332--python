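import numpy as np
import pytest

from condorcircuit.raster import CovariateStack, Raster
from condorcircuit.synthetic import (SyntheticConfig, default_release_site,
                                     generate_landscape, simulate_telemetry,
                                     true_conductance)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(grid_rows=48, grid_cols=48, cell_size=1_000.0,
                           autocorr_range=5_000.0, decay_length=15_000.0,
                           n_birds=5, days=10, fixes_per_day=8, seed=11,
                           ocean_cols=4, n_offshore=40, n_near_site=60)


@pytest.fixture(scope="session")
def small_landscape(small_config):
    stack = generate_landscape(small_config)
    truth = true_conductance(stack, small_config.true_coefficients)
    site = default_release_site(small_config)
    return stack, truth, site


@pytest.fixture(scope="session")
def raw_telemetry(small_config, small_landscape):
    stack, truth, site = small_landscape
    table, counts = simulate_telemetry(truth, site, small_config, ocean_mask=stack.ocean)
    return table, counts


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def uniform_raster():
    return Raster(np.ones((5, 5)), 1_000.0)


def random_stack(seed: int, shape=(32, 32), names=("a", "b", "c")) -> CovariateStack:
    rng = np.random.default_rng(seed)
    template = Raster(np.zeros(shape), 1_000.0)
    return CovariateStack({n: template.like(rng.standard_normal(shape)) for n in names})
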