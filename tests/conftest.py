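import numpy as np
import pytest

from foggan import data_io, simulate


@pytest.fixture(scope="session")
def fixture_collection():
    """A small simulated corpus shared by read-only tests."""
    return simulate.make_fixture_dataset(
        n_recordings=4, freeze_prevalence=0.1, total_rows_target=10_000, seed=123
    )


@pytest.fixture(scope="session")
def preprocessed(fixture_collection):
    return data_io.preprocess(fixture_collection)


@pytest.fixture()
def two_cluster_data():
    """Linearly separable two-cluster labeled matrix (scaled-space units)."""
    rng = np.random.default_rng(42)
    n = 300
    a = rng.normal(-2.0, 0.5, size=(n, 4))
    b = rng.normal(2.0, 0.5, size=(n, 4))
    X = np.vstack([a, b])
    y = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    perm = rng.permutation(2 * n)
    return data_io.LabeledMatrix(X[perm], y[perm])
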