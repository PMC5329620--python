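import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pfclust.matrix import CANONICAL_LEVELS, ConnectivityMatrix, load_registry

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, sources=None, targets=None, canonical=True):
    values = np.asarray(values, dtype=float)
    nr, nc = values.shape
    sources = sources or [f"S{i}" for i in range(nr)]
    targets = targets or [f"T{j}" for j in range(nc)]
    return ConnectivityMatrix(
        pd.DataFrame(values, index=sources, columns=targets), canonical=canonical
    )


def random_canonical_matrix(rng, n_sources, n_targets, square=False):
    levels = np.array(CANONICAL_LEVELS, dtype=float)
    vals = rng.choice(levels, size=(n_sources, n_targets))
    if square:
        labels = [f"A{i}" for i in range(n_sources)]
        np.fill_diagonal(vals, 0.0)
        return make_matrix(vals, sources=labels, targets=labels)
    return make_matrix(vals)


@pytest.fixture
def square6(rng):
    return random_canonical_matrix(rng, 6, 6, square=True)
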