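import numpy as np
import pandas as pd
import pytest

import lakehybrid as lh
from lakehybrid.synthetic import GeneratorParams


@pytest.fixture(scope="session")
def lake():
    """Default 37-year synthetic lake (observed series + ground truth)."""
    return lh.simulate_lake(seed=1)


@pytest.fixture(scope="session")
def lake_df(lake):
    return lake[0].data


@pytest.fixture(scope="session")
def logistic_pair():
    """Unidirectionally coupled logistic maps: x forces y at strength 0.32."""
    return lh.simulate_coupled_logistic(n=1000, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def monthly_index(n, start="2000-01-01"):
    return pd.date_range(start, periods=n, freq="MS")
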