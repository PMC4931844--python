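import numpy as np
import pandas as pd
import pytest

from crnet import ExpressionMatrix, GeneNetwork


@pytest.fixture
def triangle() -> GeneNetwork:
    adj = np.zeros((3, 3))
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        adj[i, j] = adj[j, i] = 1.0
    return GeneNetwork(["a", "b", "c"], adj)


@pytest.fixture
def two_triangles() -> GeneNetwork:
    adj = np.zeros((6, 6))
    for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
        adj[i, j] = adj[j, i] = 1.0
    return GeneNetwork([f"g{i}" for i in range(6)], adj)


@pytest.fixture
def path_abc() -> GeneNetwork:
    adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return GeneNetwork(["A", "B", "C"], adj)


def random_weighted_network(n: int, seed: int, density: float = 0.4,
                            connected: bool = False) -> GeneNetwork:
    rng = np.random.default_rng(seed)
    adj = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                adj[i, j] = adj[j, i] = rng.uniform(0.1, 1.0)
    if connected:  # spanning path guarantees one component
        for i in range(n - 1):
            if adj[i, i + 1] == 0:
                adj[i, i + 1] = adj[i + 1, i] = rng.uniform(0.1, 1.0)
    return GeneNetwork([f"g{i}" for i in range(n)], adj)


def expression_from_array(x: np.ndarray, treatment: str = "A") -> ExpressionMatrix:
    genes = [f"g{i}" for i in range(x.shape[0])]
    samples = [f"s{j}" for j in range(x.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(x, index=genes, columns=samples),
        pd.Series([treatment] * x.shape[1], index=samples),
    )
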