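"""Shared fixtures and independent brute-force oracles."""

import numpy as np
import pytest

from wtonet import AdjacencyMatrix, ExpressionMatrix, FixtureSpec, \
    make_block_expression


def naive_wto(A: np.ndarray, i: int, j: int) -> float:
    """Triple-loop evaluation of the wTO score, independent of the
    vectorized implementation."""
    n = A.shape[0]
    k = [sum(abs(A[a][b]) for b in range(n)) for a in range(n)]
    numer = sum(A[i][u] * A[u][j] for u in range(n)) + A[i][j]
    denom = min(k[i], k[j]) + 1.0 - abs(A[i][j])
    if denom == 0:
        return A[i][j]
    return numer / denom


def naive_wto_self(A: np.ndarray, i: int) -> float:
    n = A.shape[0]
    k_i = sum(abs(A[i][u]) for u in range(n))
    return sum(A[i][u] ** 2 for u in range(n)) / (k_i + 1.0)


def random_adjacency(rng: np.random.Generator, n: int) -> AdjacencyMatrix:
    raw = rng.uniform(-1, 1, size=(n, n))
    A = (raw + raw.T) / 2
    np.fill_diagonal(A, 0.0)
    ids = tuple(f"g{i}" for i in range(n))
    return AdjacencyMatrix(ids, A)


@pytest.fixture(scope="session")
def two_block_expr() -> ExpressionMatrix:
    """Planted two-module expression matrix shared across power tests."""
    spec = FixtureSpec(n_nodes=60, n_samples=100, n_modules=2,
                       within_module_correlation=0.7,
                       between_module_correlation=0.0, seed=7)
    return make_block_expression(spec)


@pytest.fixture(scope="session")
def independent_expr() -> ExpressionMatrix:
    """Independent Gaussian rows: no true links anywhere."""
    spec = FixtureSpec(n_nodes=30, n_samples=50, n_modules=1,
                       within_module_correlation=0.0, seed=11)
    return make_block_expression(spec)
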