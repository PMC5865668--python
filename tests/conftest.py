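import numpy as np
import pandas as pd
import pytest

from rppaflow.normalization import NON_SCC, SCC, ExpressionMatrix
from rppaflow.synthetic_data import GrowthParams, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_free_slide_config():
    return SimulationConfig(seed=7, slide_params=(100.0, 1000.0, 1.0, 0.0))


@pytest.fixture
def small_matrix():
    values = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 0.5],
            "s2": [2.0, 4.0, 1.5],
            "s3": [3.0, 6.0, 2.5],
        },
        index=["p1", "p2", "p3"],
    )
    return ExpressionMatrix(
        values=values,
        histology={"s1": SCC, "s2": NON_SCC, "s3": NON_SCC},
        base_sample={s: s for s in values.columns},
    )


@pytest.fixture
def growth_config():
    return SimulationConfig(
        seed=42,
        growth_params=GrowthParams(
            structure="ar1", rho=0.5, sigma=20.0, n_per_group=5,
            days=(0, 3, 7, 10, 14, 17, 21),
        ),
    )
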