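import numpy as np
import pandas as pd
import pytest

from gmediate import CohortTable, default_pelotas_params, generate_cohort


@pytest.fixture(scope="session")
def params():
    return default_pelotas_params()


@pytest.fixture(scope="session")
def cohort4599(params):
    """A study-sized synthetic cohort, fully observed."""
    return generate_cohort(params, 4599, seed=11)


@pytest.fixture(scope="session")
def cohort_large(params):
    """A 100k cohort for low-noise checks."""
    return generate_cohort(params, 100_000, seed=29)


def make_2x2_cohort(a: int, b: int, c: int, d: int) -> CohortTable:
    """Binary cohort from 2x2 counts: a=exposed cases, b=exposed noncases,
    c=unexposed cases, d=unexposed noncases."""
    x = [1.0] * (a + b) + [0.0] * (c + d)
    y = [1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d
    df = pd.DataFrame({"x": x, "y": y})
    return CohortTable(df, {"x": "exposure", "y": "outcome"})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
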