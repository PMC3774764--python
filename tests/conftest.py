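import numpy as np
import pandas as pd
import pytest

from ecostunt import ChildGenParams, DistrictGenParams, gen_children, gen_districts
from ecostunt import children_to_frame, districts_to_frame


@pytest.fixture(scope="session")
def district_frame():
    """One seeded default synthetic district table (n = 112)."""
    return districts_to_frame(gen_districts(DistrictGenParams(seed=7)))


@pytest.fixture(scope="session")
def child_frame():
    """A small seeded child table: 50 PSUs, 20 children each."""
    params = ChildGenParams(n_psu=50, children_per_psu=20, seed=11)
    return children_to_frame(gen_children(params))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_regression_frame():
    """5-row fixture whose bivariate OLS solution is known in closed form:
    slope 0.8, intercept 0.6 (hand-solved normal equations)."""
    return pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "y": [1.0, 3, 2, 5, 4]})
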