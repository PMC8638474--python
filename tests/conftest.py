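import numpy as np
import pandas as pd
import pytest

from qintreg import GeneratorConfig, build_region_graph, generate_dataset
from qintreg.engine import MCMCSettings
from qintreg.synthetic import AnalysisDataset


@pytest.fixture(scope="session")
def namibia():
    return build_region_graph("namibia13")


@pytest.fixture(scope="session")
def ring4():
    return build_region_graph("ring4")


@pytest.fixture(scope="session")
def small_dataset(namibia):
    """~600-record default-config dataset shared across tests."""
    return generate_dataset(GeneratorConfig(n_per_year=200, seed=11), namibia)


@pytest.fixture
def quick_mcmc():
    return MCMCSettings(iterations=600, burn_in=200)


def make_plain_dataset(y, **extra):
    """Minimal single-year dataset around an outcome vector."""
    n = len(y)
    cols = {
        "bmiaz": np.asarray(y, dtype=float),
        "year": 2013,
        "child_age_months": np.zeros(n, dtype=int),
        "preceding_birth_interval_months": pd.array([12] * n, dtype="Int64"),
        "region_id": "R1",
    }
    cols.update(extra)
    return AnalysisDataset(pd.DataFrame(cols))
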