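import numpy as np
import pandas as pd
import pytest

from latebloom.signatures import ExpressionMatrix


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    # 3 genes x 2 samples with columns (1,3,5) and (2,4,6)
    return ExpressionMatrix(
        ["G1", "G2", "G3"], ["A", "B"],
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
    )


@pytest.fixture
def km_fixture() -> pd.DataFrame:
    return pd.DataFrame({
        "time_years": [1.0, 2.0, 2.0, 3.0, 4.0],
        "event": [1, 1, 1, 0, 1],
    })


@pytest.fixture
def cox12_fixture() -> pd.DataFrame:
    """12 records, one binary covariate, with tied event times."""
    return pd.DataFrame({
        "time_years": [1, 1, 2, 3, 3, 4, 5, 6, 7, 8, 9, 10],
        "event":      [1, 0, 1, 1, 1, 0, 1, 0, 1, 1, 0, 0],
        "x":          [1.0, 0, 1, 1, 0, 0, 1, 0, 0, 1, 0, 1],
    })


def two_group_exponential(rng: np.random.Generator, n: int,
                          lam0: float = 0.15, hr: float = 1.0,
                          horizon: float = 10.0) -> pd.DataFrame:
    """Exponential survival with a binary covariate of known hazard ratio."""
    x = rng.binomial(1, 0.5, n).astype(float)
    lam = lam0 * np.where(x == 1, hr, 1.0)
    t = rng.exponential(1.0 / lam)
    c = np.minimum(rng.uniform(0, 2 * horizon, n), horizon)
    return pd.DataFrame({
        "time_years": np.maximum(np.minimum(t, c), 1e-9),
        "event": (t <= c).astype(int),
        "x": x,
    })
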