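import numpy as np
import pandas as pd
import pytest

from boolinfer.data_io import LOG_RATIO, ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 4 timepoints, log-ratio scale."""
    df = pd.DataFrame(
        [[0.0, 2.0, 1.0, -1.0], [1.0, 5.0, 3.0, 2.0], [-0.5, 0.2, 0.0, 0.4]],
        index=["A", "B", "C"],
        columns=["t0", "t1", "t2", "t3"],
    )
    return ExpressionMatrix(df, data_kind=LOG_RATIO)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
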