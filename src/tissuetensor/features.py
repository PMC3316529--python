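"""Graph-theoretic feature extraction from cell-graphs.

Computes the 26-entry feature vector used throughout the analyses --
connectivity indicators (degree, clustering coefficients, giant connected
component), distance indicators (eccentricity, diameter, radius and their
90%-quantile variants, path length, hop-plot statistics) and compactness
indicators (isolated/end/central points, edge-length statistics) -- plus
optional spectral descriptors of the graph Laplacian.

Distance features are computed within connected components (over finite
shortest-path distances only).  Undefined quantities (empty or edgeless
graphs) are reported as NaN rather than raising.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components, shortest_path

from .cellgraph import CellGraph

#: Canonical feature order; feature tables always use this column order.
FEATURE_NAMES: tuple[str, ...] = (
    "average degree",
    "clustering coefficient C",
    "clustering coefficient D",
    "clustering coefficient E",
    "average eccentricity",
    "diameter",
    "radius",
    "average eccentricity 90",
    "diameter 90",
    "radius 90",
    "average path length",
    "effective hop diameter",
    "hop plot exponent",
    "giant connected component ratio",
    "number of connected components",
    "average connected component size",
    "percent isolated points",
    "percent end points",
    "number of central points",
    "percent central points",
    "mean",
    "std",
    "skewness",
    "kurtosis",
    "number of nodes",
    "number of edges",
)

#: Outlier features dropped before factorization (26 - 3 = 23 remain).
DEFAULT_EXCLUSIONS: tuple[str, ...] = (
    "effective hop diameter",
    "number of central points",
    "percent central points",
)

SPECTRAL_NAMES: tuple[str, ...] = (
    "spectral radius",
    "eigen exponent",
    "number of zero laplacian eigenvalues",
)


def _finite_distance_matrix(graph: CellGraph) -> np.ndarray:
    """All-pairs hop distances (unweighted BFS); inf for unreachable pairs."""
    A = graph.adjacency()
    return shortest_path(A, method="D", unweighted=True, directed=False)


def hop_plot(graph: CellGraph) -> tuple[pd.DataFrame, float, float]:
    """Hop-plot: reachable ordered pairs within h hops, and its summaries.

    Returns ``(table, hop_plot_exponent, effective_hop_diameter)``.  N(h) is
    the number of ordered node pairs (u != v) with hop distance <= h, for
    h = 1..max finite eccentricity; N(inf) counts all finite pairs.  The
    exponent is the log-log least-squares slope over hops with N(h) < N(inf);
    the effective hop diameter is the smallest (linearly interpolated) h with
    N(h) >= 0.9 N(inf), floored at 1.
    """
    if graph.n_nodes < 2:
        raise ValueError("hop plot requires at least 2 nodes")
    if graph.n_edges == 0:
        empty = pd.DataFrame({"h": [], "n_pairs": []})
        return empty, float("nan"), float("nan")
    D = _finite_distance_matrix(graph)
    finite = np.isfinite(D) & (D > 0)
    n_inf = int(finite.sum())
    hmax = int(D[finite].max())
    hs = np.arange(1, hmax + 1)
    counts = np.array([int((finite & (D <= h)).sum()) for h in hs])
    table = pd.DataFrame({"h": hs, "n_pairs": counts})
    grow = counts < n_inf
    if grow.sum() >= 2:
        slope = np.polyfit(np.log(hs[grow]), np.log(counts[grow]), 1)[0]
        exponent = float(slope)
    elif grow.sum() == 1:
        # single growing point: slope from (h, N(h)) to (h+1, N(inf))
        h0, c0 = hs[grow][0], counts[grow][0]
        exponent = float((np.log(n_inf) - np.log(c0)) / (np.log(h0 + 1) - np.log(h0)))
    else:
        exponent = float("nan")
    target = 0.9 * n_inf
    idx = int(np.argmax(counts >= target))
    if counts[idx] >= target and idx == 0:
        eff = 1.0
    else:
        c_lo, c_hi = counts[idx - 1], counts[idx]
        eff = float(hs[idx - 1] + (target - c_lo) / (c_hi - c_lo))
    return table, exponent, eff


def laplacian_spectrum(graph: CellGraph, normalized: bool = True) -> np.ndarray:
    """Ascending eigenvalues of the (normalized) graph Laplacian.

    The normalized spectrum lies in [0, 2] and its zero eigenvalues count the
    connected components, which makes spectra of differently sized graphs
    comparable.  Isolated nodes contribute a zero row (eigenvalue 0).
    """
    n = graph.n_nodes
    if n == 0:
        raise ValueError("empty graph has no spectrum")
    A = graph.adjacency().toarray()
    deg = A.sum(axis=1)
    if normalized:
        with np.errstate(divide="ignore"):
            inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
        L = np.eye(n) - inv_sqrt[:, None] * A * inv_sqrt[None, :]
        L[deg == 0, :] = 0.0
        L[:, deg == 0] = 0.0
    else:
        L = np.diag(deg) - A
    return np.sort(np.linalg.eigvalsh((L + L.T) / 2.0))


def count_zero_eigenvalues(eigvals: np.ndarray, n: int) -> int:
    """Zero eigenvalues at tolerance 1e-8 * n (equals # connected components)."""
    return int((np.abs(eigvals) < 1e-8 * max(n, 1)).sum())


def _edge_length_stats(lengths: np.ndarray) -> tuple[float, float, float, float]:
    """Mean/std/skewness/Pearson-kurtosis of the edge-length multiset.

    Skewness is the standardized third central moment; kurtosis is the
    non-excess (Pearson) fourth standardized moment, so a normal sample sits
    near 3.  Population (biased) normalization throughout.
    """
    if lengths.size == 0:
        return (float("nan"),) * 4
    m = lengths.mean()
    sd = lengths.std()
    if sd == 0:
        return float(m), 0.0, float("nan"), float("nan")
    z = (lengths - m) / sd
    return float(m), float(sd), float((z**3).mean()), float((z**4).mean())


def compute_features(graph: CellGraph, spectral: bool = False) -> pd.Series:
    """Compute the full cell-graph feature vector.

    Returns a Series indexed by :data:`FEATURE_NAMES` (plus
    :data:`SPECTRAL_NAMES` when ``spectral=True``).  Distance features use
    finite hop distances only, so disconnected graphs remain well defined;
    empty / edgeless graphs yield NaN for the undefined entries.
    """
    n = graph.n_nodes
    m = graph.n_edges
    out = dict.fromkeys(FEATURE_NAMES, float("nan"))
    out["number of nodes"] = float(n)
    out["number of edges"] = float(m)
    if n == 0:
        warnings.warn("empty graph: all features undefined", stacklevel=2)
        return pd.Series(out, dtype=float)

    deg = graph.degrees()
    out["average degree"] = 2.0 * m / n
    out["percent isolated points"] = 100.0 * (deg == 0).sum() / n
    out["percent end points"] = 100.0 * (deg == 1).sum() / n

    # connected components
    A = graph.adjacency()
    n_comp, comp_labels = connected_components(A, directed=False)
    sizes = np.bincount(comp_labels)
    out["number of connected components"] = float(n_comp)
    out["average connected component size"] = float(sizes.mean())
    out["giant connected component ratio"] = float(sizes.max() / n)

    # clustering coefficients (three conventions)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    G.add_edges_from(map(tuple, graph.edges))
    local = nx.clustering(G)
    deg_ge2 = [v for v in G.nodes if deg[v] >= 2]
    out["clustering coefficient C"] = (
        float(np.mean([local[v] for v in deg_ge2])) if deg_ge2 else float("nan")
    )
    out["clustering coefficient D"] = (
        float(nx.transitivity(G)) if m > 0 else float("nan")
    )
    non_isolated = [v for v in G.nodes if deg[v] >= 1]
    out["clustering coefficient E"] = (
        float(np.mean([local[v] for v in non_isolated])) if non_isolated else float("nan")
    )

    # distance features over finite pairs
    if m > 0:
        D = _finite_distance_matrix(graph)
        finite = np.isfinite(D) & (D > 0)
        has_neighbor = finite.any(axis=1)
        ecc = np.zeros(n)
        ecc90 = np.zeros(n)
        for v in range(n):
            if not has_neighbor[v]:
                continue  # isolated: eccentricity 0 within its own component
            dv = D[v][finite[v]]
            ecc[v] = dv.max()
            # smallest h covering >= 90% of nodes reachable from v
            srt = np.sort(dv)
            k = int(np.ceil(0.9 * len(srt)))
            ecc90[v] = srt[k - 1]
        out["average eccentricity"] = float(ecc.mean())
        out["diameter"] = float(ecc.max())
        out["radius"] = float(ecc.min())
        out["average eccentricity 90"] = float(ecc90.mean())
        out["diameter 90"] = float(ecc90.max())
        out["radius 90"] = float(ecc90.min())
        out["average path length"] = float(D[finite].mean())
        central = ecc == out["radius"]
        out["number of central points"] = float(central.sum())
        out["percent central points"] = 100.0 * central.sum() / n
        try:
            _, exponent, eff = hop_plot(graph)
            out["hop plot exponent"] = exponent
            out["effective hop diameter"] = eff
        except ValueError:
            pass
    else:
        warnings.warn(
            "graph has no edges: distance and edge-length features undefined",
            stacklevel=2,
        )

    mean, sd, skew, kurt = _edge_length_stats(graph.lengths)
    out["mean"] = mean
    out["std"] = sd
    out["skewness"] = skew
    out["kurtosis"] = kurt

    series = pd.Series(out, dtype=float).reindex(list(FEATURE_NAMES))
    if spectral:
        series = pd.concat([series, _spectral_features(graph)])
    return series


def _spectral_features(graph: CellGraph) -> pd.Series:
    """Spectral radius, eigen exponent, zero-Laplacian-eigenvalue count."""
    n = graph.n_nodes
    out = dict.fromkeys(SPECTRAL_NAMES, float("nan"))
    if n == 0:
        return pd.Series(out, dtype=float)
    A = graph.adjacency().toarray()
    eig = np.linalg.eigvalsh((A + A.T) / 2.0)
    out["spectral radius"] = float(np.abs(eig).max())
    # eigen exponent: log-log slope of the top 20% of descending eigenvalues
    desc = np.sort(eig)[::-1]
    top = desc[: max(2, int(np.ceil(0.2 * len(desc))))]
    top = top[top > 1e-12]
    if len(top) >= 2:
        ranks = np.arange(1, len(top) + 1)
        out["eigen exponent"] = float(np.polyfit(np.log(ranks), np.log(top), 1)[0])
    lap = laplacian_spectrum(graph, normalized=True)
    out["number of zero laplacian eigenvalues"] = float(count_zero_eigenvalues(lap, n))
    return pd.Series(out, dtype=float)


def compute_feature_table(
    graphs: Iterable[CellGraph], spectral: bool = False
) -> pd.DataFrame:
    """Feature table, one row per graph, with sample metadata columns first."""
    rows = []
    meta = []
    for g in graphs:
        rows.append(compute_features(g, spectral=spectral))
        meta.append(
            {
                "sample_id": g.metadata.get("sample_id", ""),
                "label": g.metadata.get("label", ""),
                "time_hours": g.metadata.get("time_hours", float("nan")),
            }
        )
    feats = pd.DataFrame(rows).reset_index(drop=True)
    return pd.concat([pd.DataFrame(meta), feats], axis=1)


def apply_exclusions(
    table: pd.DataFrame, excluded: Sequence[str] = DEFAULT_EXCLUSIONS
) -> pd.DataFrame:
    """Drop excluded feature columns (default: the three outlier features).

    With the default list the 26 features reduce to 23.  Unknown names and
    exclusion of every feature column raise.
    """
    feature_cols = [c for c in table.columns if c in FEATURE_NAMES or c in SPECTRAL_NAMES]
    unknown = [e for e in excluded if e not in FEATURE_NAMES and e not in SPECTRAL_NAMES]
    if unknown:
        raise ValueError(f"unknown feature names in exclusion list: {unknown}")
    remaining = [c for c in feature_cols if c not in set(excluded)]
    if not remaining:
        raise ValueError("exclusion list removes every feature column")
    keep = [c for c in table.columns if c not in set(excluded)]
    return table[keep]
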