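import logging

import numpy as np
import pandas as pd
import pytest

from polynest.events import build_survival_records
from polynest.simulate import SimConfig, simulate_timeseries

logging.getLogger("polynest").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_sim():
    """Default-scale simulation (13 colonies, 5 timepoints) shared across
    tests; planted effects at their default values."""
    series, truth = simulate_timeseries(SimConfig(seed=0))
    return series, truth


@pytest.fixture(scope="session")
def default_records(default_sim):
    series, _ = default_sim
    return pd.concat(
        [build_survival_records(ts) for ts in series], ignore_index=True
    )


@pytest.fixture(scope="session")
def small_sim():
    """Small, fast simulation (4 colonies) for structural tests."""
    series, truth = simulate_timeseries(SimConfig(n_colonies=4, seed=42))
    return series, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
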