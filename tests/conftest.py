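import numpy as np
import pandas as pd
import pytest

import wpcna


@pytest.fixture(scope="session")
def small_study():
    """A compact planted study reused by read-only tests."""
    return wpcna.simulate_study(
        n_peptides=300, module_sizes=(60, 30), within_module_cor=0.6,
        trait_cor=0.7, seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def two_block_dissimilarity():
    """Perfect two-module structure: D = 0 within blocks, 1 between."""
    n = 20
    D = np.ones((n, n))
    D[:10, :10] = 0.0
    D[10:, 10:] = 0.0
    np.fill_diagonal(D, 0.0)
    ids = [f"pep{i:02d}" for i in range(n)]
    return pd.DataFrame(D, index=ids, columns=ids)


def random_adjacency(rng, n):
    """Symmetric adjacency with entries in [0, 1] and unit diagonal."""
    M = rng.random((n, n))
    A = (M + M.T) / 2.0
    np.fill_diagonal(A, 1.0)
    return A


def tom_loop_oracle(A):
    """Brute-force triple-loop topological overlap (test oracle)."""
    n = A.shape[0]
    k = np.array([sum(A[i, u] for u in range(n) if u != i) for i in range(n)])
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            num += A[i, j]
            den = min(k[i], k[j]) + 1.0 - A[i, j]
            T[i, j] = num / den
    return T
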