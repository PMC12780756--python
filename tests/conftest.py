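import dataclasses

import numpy as np
import pytest

from hetforest import synthetic
from hetforest.config import ForestParams


@pytest.fixture(scope="session")
def default_cfg():
    """The full-size calibrated generator configuration (cached)."""
    return synthetic.default_config()


@pytest.fixture(scope="session")
def small_cfg():
    """A down-scaled calibrated design for cheap end-to-end tests."""
    base = dataclasses.replace(synthetic.DGPConfig(), n_treated=500,
                               n_control_pool=30_000)
    return synthetic.calibrate(base)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return synthetic.generate_cohort(small_cfg, seed=17)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def fast_params():
    """Small forest for unit tests where statistical power is not the point."""
    return ForestParams(n_trees=50, min_node_size=10)
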