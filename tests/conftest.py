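import warnings

import numpy as np
import pytest

from honmf import HONMF, simulate_multiomics

FEATURES = [40, 30, 20]
N_SAMPLES = 30
N_CLUSTERS = 3


def fit_synthetic(seed, separation=1.0, features=FEATURES, variant="honmf", **kw):
    """One full pipeline run on the standard synthetic configuration."""
    ds, truth = simulate_multiomics(N_SAMPLES, N_CLUSTERS, features, separation, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = HONMF(ds, k=N_CLUSTERS, seed=seed, variant=variant, **kw).fit()
    return ds, truth, res


@pytest.fixture(scope="session")
def fitted_grid():
    """Fits at full separation for seeds 0-9, shared across tests."""
    return {seed: fit_synthetic(seed) for seed in range(10)}


@pytest.fixture()
def small_dataset():
    ds, truth = simulate_multiomics(N_SAMPLES, N_CLUSTERS, FEATURES, 1.0, seed=0)
    return ds, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_hypergraph(rng, n=None):
    """Random valid hypergraph: covering hyperedges of size >= 2."""
    from honmf import Hypergraph

    if n is None:
        n = int(rng.integers(4, 13))
    n_edges = int(rng.integers(1, 5))
    P = np.zeros((n, n_edges))
    for e in range(n_edges):
        size = int(rng.integers(2, n + 1))
        members = rng.choice(n, size=size, replace=False)
        P[members, e] = 1.0
    # ensure every vertex is covered
    for v in range(n):
        if P[v].sum() == 0:
            P[v, rng.integers(0, n_edges)] = 1.0
    # re-check min hyperedge size after coverage fill (always grows, fine)
    w = rng.uniform(0.2, 3.0, size=n_edges)
    return Hypergraph(P, w)
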