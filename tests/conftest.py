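"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from tissuetensor.cellgraph import CellGraph


def graph_from_topology(
    edges: list[tuple[int, int]], n: int, rng: np.random.Generator | None = None
) -> CellGraph:
    """Build a CellGraph with arbitrary topology; coordinates are random (or
    deterministic) and edge lengths follow from them, so hop-based features
    only depend on the supplied edge list."""
    if rng is None:
        coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        coords[:, 1] = (np.arange(n) % 7) * 0.37  # avoid exact collinearity
    else:
        coords = rng.uniform(0, 100, size=(n, 2))
    e = np.array(edges, dtype=int).reshape(-1, 2)
    lengths = (
        np.linalg.norm(coords[e[:, 0]] - coords[e[:, 1]], axis=1)
        if e.size
        else np.empty(0)
    )
    return CellGraph(coords=coords, edges=e, lengths=lengths)


def random_graph(rng: np.random.Generator, n_max: int = 30, p: float | None = None) -> CellGraph:
    """Random Erdos-Renyi-style spatial graph with <= n_max nodes."""
    n = int(rng.integers(2, n_max + 1))
    if p is None:
        p = float(rng.uniform(0.05, 0.5))
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
    ]
    return graph_from_topology(edges, n, rng)


def bfs_distances(n: int, edges: np.ndarray) -> np.ndarray:
    """Pure-python BFS all-pairs hop distances; np.inf when unreachable."""
    adj: list[list[int]] = [[] for _ in range(n)]
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    D = np.full((n, n), np.inf)
    for s in range(n):
        D[s, s] = 0
        q = deque([s])
        while q:
            u = q.popleft()
            for w in adj[u]:
                if not np.isfinite(D[s, w]):
                    D[s, w] = D[s, u] + 1
                    q.append(w)
    return D


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
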