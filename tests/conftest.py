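import numpy as np
import pandas as pd
import pytest

from meningiomics.expression_subtyping import CountMatrix
from meningiomics.synthetic_cohort import CohortConfig, simulate_expression


@pytest.fixture(scope="session")
def default_cohort():
    """One default-config expression cohort shared across read-only tests."""
    cfg = CohortConfig(seed=123)
    counts, truth = simulate_expression(cfg)
    return cfg, counts, truth


@pytest.fixture()
def toy_counts():
    """3x3 count matrix small enough for hand calculations."""
    values = np.array([[10, 20, 40], [6, 12, 24], [100, 200, 400]])
    return CountMatrix(values, ["g1", "g2", "g3"], ["s1", "s2", "s3"])


@pytest.fixture()
def toy_survival():
    """5-record table with one censoring, for hand product-limit checks."""
    return pd.DataFrame(
        {
            "sample": [f"p{i}" for i in range(1, 6)],
            "time": [2.0, 4.0, 4.0, 6.0, 9.0],
            "event": [True, True, False, True, False],
            "group": ["A"] * 5,
        }
    )
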