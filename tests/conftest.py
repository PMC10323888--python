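import numpy as np
import pandas as pd
import pytest

from stromasig import ExpressionMatrix, SurvivalTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_matrix():
    """2 genes x 3 samples, trivially checkable by hand."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
            index=["GENEA", "GENEB"],
            columns=["S1", "S2", "S3"],
        )
    )


def make_survival(time, event, ids=None, **covariates):
    ids = ids or [f"s{i}" for i in range(len(time))]
    df = pd.DataFrame({"sample_id": ids, "time": time, "event": event})
    for name, values in covariates.items():
        df[name] = values
    return SurvivalTable(df)


@pytest.fixture
def toy_survival():
    """4 subjects, one censored at t=2: hand product-limit 3/4, 1/2, 0."""
    return make_survival([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 1])
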