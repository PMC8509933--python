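import numpy as np
import pandas as pd
import pytest

from czscaling import SyntheticConfig, generate, make_loglog


@pytest.fixture
def toy_counties():
    """6 counties in 3 units over 2 years with hand-set values."""
    pills = pd.DataFrame({
        "county_fips": ["01001", "01002", "02001", "02002", "03001", "03002",
                        "01001", "01002", "02001", "02002", "03001", "03002"],
        "year": [2006] * 6 + [2007] * 6,
        "pills": [100, 200, 300, 400, 500, 600,
                  110, 210, 310, 410, 510, 610],
    })
    pops = pd.DataFrame({
        "county_fips": pills["county_fips"],
        "year": pills["year"],
        "population": [1000, 2000, 3000, 4000, 5000, 6000,
                       1100, 2100, 3100, 4100, 5100, 6100],
    })
    xwalk = pd.DataFrame({
        "county_fips": ["01001", "01002", "02001", "02002", "03001", "03002"],
        "unit_id": ["A", "A", "B", "B", "C", "C"],
        "unit_kind": "CZ",
        "state": ["OH", "OH", "TX", "TX", "CA", "CA"],
    })
    return pills, pops, xwalk


@pytest.fixture
def default_dataset():
    return generate(SyntheticConfig(seed=42))


@pytest.fixture
def default_frame(default_dataset):
    return make_loglog(default_dataset.units)


@pytest.fixture
def small_frame():
    """8-point deterministic log-log frame with points on both knot sides."""
    rng = np.random.default_rng(7)
    x = np.linspace(np.log(1e4), np.log(1e6), 8)
    y = 2.0 + 1.1 * x + rng.normal(0, 0.2, 8)
    return pd.DataFrame({"unit_id": [f"u{i}" for i in range(8)], "x": x, "y": y})


def ols_oracle(X, y):
    """Independent normal-equations solver: beta = (X'X)^{-1} X'y.

    Deliberately avoids statsmodels and lstsq so it cannot share a code
    path with the implementation under test.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xtx = np.zeros((X.shape[1], X.shape[1]))
    xty = np.zeros(X.shape[1])
    for i in range(len(y)):          # explicit summation, no BLAS shortcut
        xtx += np.outer(X[i], X[i])
        xty += X[i] * y[i]
    return np.linalg.solve(xtx, xty)
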