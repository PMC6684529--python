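import numpy as np
import pytest

import eslreg as E


def random_instance(seed: int, n: int = 8, p: int = 3):
    """Small random regression problem with intercept; returns
    (RegressionData, beta_at_which_to_evaluate)."""
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    beta_true = rng.standard_normal(p)
    y = X @ beta_true + rng.standard_normal(n)
    beta_eval = beta_true + 0.3 * rng.standard_normal(p)
    return E.RegressionData(y, X), beta_eval


@pytest.fixture
def exact_fit_data():
    rng = np.random.default_rng(7)
    X = np.column_stack([np.ones(30), rng.standard_normal((30, 2))])
    beta = np.array([2.0, 1.0, -1.0])
    return E.RegressionData(X @ beta, X), beta


@pytest.fixture
def clean_small():
    rng = np.random.default_rng(42)
    X = np.column_stack([np.ones(40), rng.standard_normal((40, 2))])
    beta = np.array([1.0, -2.0, 0.5])
    y = X @ beta + 0.1 * rng.standard_normal(40)
    return E.RegressionData(y, X), beta
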