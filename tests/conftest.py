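import numpy as np
import pandas as pd
import pytest

from heattwin import synthetic


@pytest.fixture(scope="session")
def benchmark_dir(tmp_path_factory):
    """One shared benchmark-week bundle (seed 11) for integration tests."""
    out = tmp_path_factory.mktemp("bench")
    paths = synthetic.make_benchmark_week(seed=11, out_dir=out)
    return paths


@pytest.fixture
def hourly_index():
    def make(n, start="2020-08-16"):
        return pd.date_range(start, periods=n, freq="1h")
    return make


@pytest.fixture
def ar1():
    """Simulate a zero-mean AR(1) path with the given coefficient."""
    def make(phi, n, seed, sd=1.0):
        rng = np.random.default_rng(seed)
        x = np.empty(n)
        x[0] = rng.normal(0, sd / np.sqrt(1 - phi**2))
        for i in range(1, n):
            x[i] = phi * x[i - 1] + rng.normal(0, sd)
        return x
    return make
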