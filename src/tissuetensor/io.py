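"""Readers and writers for every on-disk format the pipeline touches.

Formats: point-pattern CSV (``sample_id,label,time_hours,x_um,y_um``),
GraphML and edge-list/node CSV for cell-graphs, feature-table CSV (columns in
the canonical feature order), tensors as HDF5 with a JSON sidecar of mode
labels, and factor models as HDF5 or JSON.  Write -> read round trips are
lossless (bit-exact for integers/labels, <= 1e-12 relative for reals).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import networkx as nx
import numpy as np
import pandas as pd

from .analysis import FeatureMatrix, FeatureTensor
from .cellgraph import CellGraph
from .factorization import CMTFModel, CPModel
from .features import FEATURE_NAMES, SPECTRAL_NAMES
from .pattern import PointPattern

POINT_COLUMNS = ["sample_id", "label", "time_hours", "x_um", "y_um"]


# ---------------------------------------------------------------------------
# Point patterns


def write_point_patterns(patterns: Sequence[PointPattern], path: str | Path) -> None:
    rows = []
    for p in patterns:
        t = p.time_hours if p.time_hours is not None else np.nan
        for x, y in p.coordinates:
            rows.append((p.sample_id, p.label, t, x, y))
        if p.n_points == 0:  # keep empty patterns visible in the file
            rows.append((p.sample_id, p.label, t, np.nan, np.nan))
    pd.DataFrame(rows, columns=POINT_COLUMNS).to_csv(path, index=False)


def read_point_patterns(
    path: str | Path, field_size: tuple[float, float]
) -> list[PointPattern]:
    """Read patterns grouped by (sample_id, label, time); the field size is
    not stored in the CSV schema and must be supplied."""
    df = pd.read_csv(path)
    missing = [c for c in POINT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"point-pattern CSV missing column(s) {missing} in {path}")
    patterns = []
    for (sid, label, t), grp in df.groupby(
        ["sample_id", "label", "time_hours"], dropna=False, sort=True
    ):
        coords = grp[["x_um", "y_um"]].dropna().to_numpy(dtype=float)
        patterns.append(
            PointPattern(
                coordinates=coords,
                field_size=field_size,
                label=str(label),
                time_hours=None if pd.isna(t) else float(t),
                sample_id=str(sid),
            )
        )
    return patterns


# ---------------------------------------------------------------------------
# Graphs


def write_graphml(graph: CellGraph, path: str | Path) -> None:
    nx.write_graphml(graph.to_networkx(), path)


def read_graphml(path: str | Path) -> CellGraph:
    G = nx.read_graphml(path)
    G = nx.relabel_nodes(G, {n: int(n) for n in G.nodes})
    return CellGraph.from_networkx(G)


def write_edge_list(graph: CellGraph, edge_path: str | Path, node_path: str | Path) -> None:
    pd.DataFrame(
        {"u": graph.edges[:, 0], "v": graph.edges[:, 1], "length_um": graph.lengths}
    ).to_csv(edge_path, index=False)
    pd.DataFrame(
        {"node": np.arange(graph.n_nodes),
         "x_um": graph.coords[:, 0], "y_um": graph.coords[:, 1]}
    ).to_csv(node_path, index=False)


def read_edge_list(edge_path: str | Path, node_path: str | Path, **metadata) -> CellGraph:
    nodes = pd.read_csv(node_path)
    edges = pd.read_csv(edge_path)
    for col in ("x_um", "y_um"):
        if col not in nodes.columns:
            raise ValueError(f"node CSV missing column {col!r}")
    coords = nodes.sort_values("node")[["x_um", "y_um"]].to_numpy(dtype=float)
    e = edges[["u", "v"]].to_numpy(dtype=int) if len(edges) else np.empty((0, 2), int)
    l = edges["length_um"].to_numpy(dtype=float) if len(edges) else np.empty(0)
    return CellGraph(coords=coords, edges=e, lengths=l, metadata=metadata)


# ---------------------------------------------------------------------------
# Feature tables


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write with feature columns forced into the canonical order."""
    meta = [c for c in table.columns if c not in FEATURE_NAMES and c not in SPECTRAL_NAMES]
    feats = [c for c in list(FEATURE_NAMES) + list(SPECTRAL_NAMES) if c in table.columns]
    table[meta + feats].to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not any(c in FEATURE_NAMES for c in df.columns):
        raise ValueError(f"{path} contains no recognized feature columns")
    return df


# ---------------------------------------------------------------------------
# Tensors / matrices (HDF5 + JSON sidecar)


def write_tensor(tensor: FeatureTensor, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=tensor.values)
    sidecar = {
        "modes": ["feature", "sample", "time"],
        "feature_names": list(tensor.feature_names),
        "sample_ids": list(tensor.sample_ids),
        "times": [float(t) for t in tensor.times],
        "sample_classes": list(tensor.sample_classes),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_tensor(path: str | Path) -> FeatureTensor:
    path = Path(path)
    with h5py.File(path, "r") as f:
        values = f["values"][()]
    side = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return FeatureTensor(
        values=values,
        feature_names=side["feature_names"],
        sample_ids=side["sample_ids"],
        times=side["times"],
        sample_classes=side["sample_classes"],
    )


def write_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=matrix.values)
    sidecar = {
        "modes": ["feature", "sample"],
        "feature_names": list(matrix.feature_names),
        "sample_ids": list(matrix.sample_ids),
        "sample_classes": list(matrix.sample_classes),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    with h5py.File(path, "r") as f:
        values = f["values"][()]
    side = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return FeatureMatrix(
        values=values,
        feature_names=side["feature_names"],
        sample_ids=side["sample_ids"],
        sample_classes=side["sample_classes"],
    )


# ---------------------------------------------------------------------------
# Factor models


def write_cp_model(model: CPModel, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "cp"
        f.attrs["fit"] = model.fit
        f.attrs["n_iter"] = model.n_iter
        f.attrs["converged"] = model.converged
        f.create_dataset("weights", data=model.weights)
        for i, fac in enumerate(model.factors):
            f.create_dataset(f"factor_{i}", data=fac)


def read_cp_model(path: str | Path) -> CPModel:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "cp":
            raise ValueError(f"{path} does not hold a CP model")
        n = sum(1 for k in f.keys() if k.startswith("factor_"))
        return CPModel(
            factors=[f[f"factor_{i}"][()] for i in range(n)],
            weights=f["weights"][()],
            fit=float(f.attrs["fit"]),
            n_iter=int(f.attrs["n_iter"]),
            converged=bool(f.attrs["converged"]),
        )


def write_cmtf_model(model: CMTFModel, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "cmtf"
        f.attrs["objective"] = model.objective
        f.attrs["n_iter"] = model.n_iter
        f.attrs["converged"] = model.converged
        for name, fac in zip("ABCD", model.factors):
            f.create_dataset(name, data=fac)


def read_cmtf_model(path: str | Path) -> CMTFModel:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "cmtf":
            raise ValueError(f"{path} does not hold a CMTF model")
        return CMTFModel(
            A=f["A"][()], B=f["B"][()], C=f["C"][()], D=f["D"][()],
            objective=float(f.attrs["objective"]),
            n_iter=int(f.attrs["n_iter"]),
            converged=bool(f.attrs["converged"]),
        )
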