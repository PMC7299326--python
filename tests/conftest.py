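import numpy as np
import pandas as pd
import pytest

from fightsync import (SimParams, log_transform, normalize, simulate_counts,
                       simulate_design)


@pytest.fixture(scope="session")
def design():
    return simulate_design(5, 5)


@pytest.fixture(scope="session")
def sim_data(design):
    """Desk-scale simulated experiment shared across read-only tests."""
    params = SimParams(n_genes=600, seed=11)
    counts, truth = simulate_counts(design, params)
    return counts, truth, params


@pytest.fixture(scope="session")
def normalized(sim_data):
    counts, _, _ = sim_data
    filtered, factors, tmm = normalize(counts)
    return filtered, factors, tmm


@pytest.fixture(scope="session")
def log_tmm(normalized):
    return log_transform(normalized[2])


@pytest.fixture()
def toy_counts():
    """4-gene / 2-sample matrix where column 2 is exactly 2x column 1."""
    base = np.array([100, 500, 2000, 50])
    return pd.DataFrame({"s1": base, "s2": 2 * base},
                        index=[f"g{i}" for i in range(4)])
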