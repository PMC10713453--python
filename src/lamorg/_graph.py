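"""kNN-graph community detection shared by the pixel and window clustering."""

from __future__ import annotations

import random

import igraph as ig
import numpy as np
from sklearn.neighbors import NearestNeighbors


def knn_graph_edges(X: np.ndarray, k: int) -> np.ndarray:
    """Undirected edge list (i, j) of the k-nearest-neighbor graph (Euclidean),
    self excluded, duplicate edges collapsed."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k = min(k, n - 1)
    if k < 1:
        raise ValueError("need at least 2 points for a kNN graph")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    src = np.repeat(np.arange(n), k)
    dst = idx[:, 1:].ravel()
    pairs = np.sort(np.column_stack([src, dst]), axis=1)
    return np.unique(pairs, axis=0)


def knn_louvain(X: np.ndarray, k: int, seed: int = 0, resolution: float = 1.0) -> np.ndarray:
    """Louvain community labels on the kNN graph of the rows of X.

    python-igraph draws from Python's ``random`` module, so seeding that
    module makes the partition deterministic.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n == 1 or np.allclose(X, X[0]):
        return np.zeros(n, dtype=int)
    edges = knn_graph_edges(X, k)
    g = ig.Graph(n=n, edges=[tuple(e) for e in edges], directed=False)
    random.seed(seed)
    part = g.community_multilevel(resolution=resolution)
    return np.asarray(part.membership, dtype=int)
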