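import numpy as np
import pandas as pd
import pytest

from checkupnet import CohortTable, VariableDescriptor


@pytest.fixture
def basic_schema():
    return (
        VariableDescriptor("age", "continuous", units="years"),
        VariableDescriptor("sex", "binary", ordinal_levels=("female", "male")),
        VariableDescriptor(
            "smoking", "ordinal", ordinal_levels=("never", "previous", "current")
        ),
    )


@pytest.fixture
def small_table(basic_schema):
    data = pd.DataFrame(
        {
            "age": [40.0, 55.0, 62.0, np.nan],
            "sex": ["male", "female", "male", "female"],
            "smoking": ["never", "current", np.nan, "previous"],
        },
        index=pd.Index(["a", "b", "c", "d"], name="subject_id"),
    )
    return CohortTable(data, basic_schema, timepoint="2018")


def make_exact_correlation(R, n, rng):
    """Two vectors whose *sample* Pearson correlation is exactly R."""
    x = rng.standard_normal(n)
    e = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    e = e - e.mean()
    e = e - x * (x @ e) / (x @ x)  # orthogonalize against x
    e = e / e.std(ddof=1)
    y = R * x + np.sqrt(1 - R * R) * e
    return x, y
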