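import numpy as np
import pandas as pd
import pytest

from sdpgwr import AreaGraph, Dataset, build_area_graph


@pytest.fixture
def tiny_area_table():
    return pd.DataFrame({
        "area_id": ["a", "b", "c"],
        "y": [1.0, 2.0, 3.0],
        "x1": [0.5, -0.5, 1.5],
        "lon": [0.0, 1.0, 2.0],
        "lat": [0.0, 0.0, 0.0],
    })


@pytest.fixture
def chain_graph(tiny_area_table):
    return build_area_graph(tiny_area_table, [("a", "b"), ("b", "c")])


@pytest.fixture
def small_dataset():
    """5 areas on a line, 2 covariates, exactly reproducible."""
    rng = np.random.default_rng(42)
    n, p = 5, 2
    coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    graph = AreaGraph([f"a{i}" for i in range(n)], coords,
                      {(i, i + 1) for i in range(n - 1)})
    X = rng.standard_normal((n, p))
    beta = np.array([1.0, -2.0])
    y = X @ beta + 0.1 * rng.standard_normal(n)
    return Dataset(y=y, X=X, graph=graph)
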