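"""Cell-graph construction from nucleus point patterns.

A cell-graph G = (V, E) has one node per nucleus centroid and edges encoding
spatial proximity: either deterministic (all pairs within a micron threshold,
the convention used for H&E histology, with thresholds near the 65-75 um
radius of a spread mammalian cell) or probabilistic (link probability decays
with distance, exponentially or as a power law).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .pattern import PointPattern


@dataclass
class CellGraph:
    """Undirected spatial graph over nucleus centroids.

    ``coords`` is ``(n, 2)`` in microns; ``edges`` is ``(m, 2)`` of node
    indices with ``u < v`` and no duplicates; ``lengths`` carries the
    Euclidean edge lengths in microns.
    """

    coords: np.ndarray
    edges: np.ndarray
    lengths: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        object.__setattr__(self, "coords", coords)
        if edges.size:
            if (edges[:, 0] == edges[:, 1]).any():
                raise ValueError("self-loops are not allowed")
            edges = np.sort(edges, axis=1)
            if len(np.unique(edges, axis=0)) != len(edges):
                raise ValueError("duplicate edges are not allowed")
        object.__setattr__(self, "edges", edges)
        lengths = np.asarray(self.lengths, dtype=float).ravel()
        if lengths.shape[0] != edges.shape[0]:
            raise ValueError("one length per edge required")
        if edges.size:
            d = np.linalg.norm(coords[edges[:, 0]] - coords[edges[:, 1]], axis=1)
            if not np.allclose(d, lengths, rtol=1e-9, atol=1e-9):
                raise ValueError("edge lengths must equal endpoint Euclidean distances")
        object.__setattr__(self, "lengths", lengths)

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        if self.edges.size:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def adjacency(self):
        """Sparse symmetric 0/1 adjacency matrix (CSR)."""
        from scipy import sparse

        n = self.n_nodes
        if not self.edges.size:
            return sparse.csr_matrix((n, n))
        u, v = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * len(u))
        return sparse.csr_matrix(
            (data, (np.r_[u, v], np.r_[v, u])), shape=(n, n)
        )

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph(**self.metadata)
        for i, (x, y) in enumerate(self.coords):
            G.add_node(i, x=float(x), y=float(y))
        for (u, v), l in zip(self.edges, self.lengths):
            G.add_edge(int(u), int(v), length=float(l))
        return G

    @classmethod
    def from_networkx(cls, G: nx.Graph) -> "CellGraph":
        nodes = sorted(G.nodes)
        index = {n: i for i, n in enumerate(nodes)}
        coords = np.array([[G.nodes[n]["x"], G.nodes[n]["y"]] for n in nodes])
        edges, lengths = [], []
        for u, v, data in G.edges(data=True):
            i, j = index[u], index[v]
            edges.append((min(i, j), max(i, j)))
            lengths.append(
                data.get(
                    "length",
                    float(np.linalg.norm(coords[i] - coords[j])),
                )
            )
        return cls(
            coords=coords,
            edges=np.array(edges, dtype=int).reshape(-1, 2),
            lengths=np.array(lengths),
            metadata=dict(G.graph),
        )


def _metadata_from_pattern(points: PointPattern) -> dict:
    md = {"sample_id": points.sample_id, "label": points.label}
    if points.time_hours is not None:
        md["time_hours"] = float(points.time_hours)
    return md


def build_graph_deterministic(
    points: PointPattern, threshold: float = 65.0, strict_less: bool = False
) -> CellGraph:
    """Link every pair of nuclei closer than ``threshold`` microns.

    The comparison is inclusive (``d <= threshold``) by default so that the
    canonical integer thresholds behave identically on integer-micron grids;
    ``strict_less=True`` uses ``d < threshold``.  Coincident nuclei (d = 0)
    are always linked.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    coords = points.coordinates
    n = coords.shape[0]
    if n < 2:
        return CellGraph(coords, np.empty((0, 2), int), np.empty(0), _metadata_from_pattern(points))
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=threshold, output_type="ndarray")
    if pairs.size:
        pairs = np.sort(pairs, axis=1)
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        if strict_less:
            keep = (d < threshold) | (d == 0.0)
            pairs, d = pairs[keep], d[keep]
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        pairs, d = pairs[order], d[order]
    else:
        pairs = np.empty((0, 2), int)
        d = np.empty(0)
    return CellGraph(coords, pairs, d, _metadata_from_pattern(points))


def edge_probability(
    d: np.ndarray, kernel: str, scale: float, exponent: float = 2.0
) -> np.ndarray:
    """Link probability as a function of distance, clamped to [0, 1].

    ``exponential``: p(d) = exp(-d / scale).  ``power_law``:
    p(d) = min(1, (d / scale) ** -exponent), with p(0) = 1.
    Both are monotone non-increasing in d.
    """
    if scale <= 0:
        raise ValueError("kernel scale must be positive")
    d = np.asarray(d, dtype=float)
    if kernel == "exponential":
        return np.exp(-d / scale)
    if kernel == "power_law":
        if exponent <= 0:
            raise ValueError("power-law exponent must be positive")
        with np.errstate(divide="ignore"):
            p = np.where(d > 0, (d / scale) ** (-exponent), np.inf)
        return np.minimum(p, 1.0)
    raise ValueError(f"unknown kernel {kernel!r}; use 'exponential' or 'power_law'")


def build_graph_probabilistic(
    points: PointPattern,
    kernel: str = "exponential",
    scale: float = 65.0,
    exponent: float = 2.0,
    seed: int | np.random.SeedSequence = 0,
) -> CellGraph:
    """Link each pair independently with distance-decaying probability."""
    coords = points.coordinates
    n = coords.shape[0]
    md = _metadata_from_pattern(points)
    if n < 2:
        return CellGraph(coords, np.empty((0, 2), int), np.empty(0), md)
    iu, ju = np.triu_indices(n, k=1)
    d = np.linalg.norm(coords[iu] - coords[ju], axis=1)
    p = edge_probability(d, kernel, scale, exponent)
    rng = np.random.default_rng(seed)
    keep = rng.random(p.shape) < p
    edges = np.column_stack([iu[keep], ju[keep]])
    return CellGraph(coords, edges, d[keep], md)
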