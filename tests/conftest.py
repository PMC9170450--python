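import numpy as np
import pandas as pd
import pytest

import wetval as wv


@pytest.fixture(scope="session")
def worked_bundle():
    return wv.worked_example()


@pytest.fixture()
def rng():
    return np.random.default_rng(20130101)


@pytest.fixture()
def small_supply():
    # one wetland type providing two services with capacities 3 and 5
    return wv.SupplyMatrix(n=pd.DataFrame(
        [[3, 5]], index=["marsh"], columns=["s1", "s2"]
    ))


@pytest.fixture()
def flat_cpi():
    return wv.CpiSeries(base_year=2013,
                        index_by_year={y: 100.0 for y in range(1995, 2014)})
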