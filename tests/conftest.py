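import numpy as np
import pytest

from ricewalk import (
    AnnotationIndex,
    EdgeList,
    FunctionalNetwork,
    column_normalize,
)


@pytest.fixture
def small_index() -> AnnotationIndex:
    """g1 and g2 share f1 (2 genes) and f2 (5 genes): F(g1,g2) = 0.7."""
    pairs = [
        ("g1", "f1"), ("g2", "f1"),
        ("g1", "f2"), ("g2", "f2"), ("g3", "f2"), ("g4", "f2"), ("g5", "f2"),
        ("g3", "f3"), ("g4", "f3"), ("g5", "f3"), ("g6", "f3"),
        ("g6", "f4"),
    ]
    return AnnotationIndex.from_pairs(pairs)


@pytest.fixture
def path_graph_matrix():
    """Two-node path a-b: W = [[0, 1], [1, 0]]."""
    net = FunctionalNetwork(nodes=("a", "b"), edges={("a", "b"): 1.0})
    return column_normalize(net, mode="unweighted")


@pytest.fixture
def triangle_matrix():
    net = FunctionalNetwork(
        nodes=("a", "b", "c"),
        edges={("a", "b"): 1.0, ("a", "c"): 1.0, ("b", "c"): 1.0},
    )
    return column_normalize(net, mode="unweighted")


def random_weighted_network(rng: np.random.Generator, n: int, p: float = 0.3) -> FunctionalNetwork:
    """Random undirected graph with positive random edge weights."""
    nodes = tuple(f"n{i:03d}" for i in range(n))
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges[(nodes[i], nodes[j])] = float(rng.uniform(0.1, 2.0))
    if not edges:  # guarantee at least one edge
        edges[(nodes[0], nodes[1])] = 1.0
    return FunctionalNetwork(nodes=nodes, edges=edges)


def linear_solve_rwr(W, p0_values: np.ndarray, r: float) -> np.ndarray:
    """Independent oracle: direct solve of P = r (I - (1-r) W)^-1 P_0."""
    from scipy import sparse

    mat = W.matrix
    if sparse.issparse(mat):
        mat = mat.toarray()
    n = mat.shape[0]
    return r * np.linalg.solve(np.eye(n) - (1.0 - r) * mat, p0_values)
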