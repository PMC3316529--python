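#!/usr/bin/env python
"""How different are the cultures from the (synthetic) native tissue?

Per class, matricizes the in vitro tensor in the features mode, concatenates
it with the histology matrix, and computes the SVD of the combined matrix:
if the first two components linearly separate the two sources, the culture
model is structurally distinguishable from native tissue.  Also compares
cumulative explained-variance curves between classes and sources.

Run:  python analysis/05_cluster_sources.py
"""

import json
import importlib.util
import warnings
from pathlib import Path

import numpy as np

import tissuetensor as tt
from tissuetensor import matricize

RESULTS = Path(__file__).resolve().parent.parent / "results"

_spec = importlib.util.spec_from_file_location(
    "cmtf_coupled", Path(__file__).with_name("04_cmtf_coupled.py")
)
_cmtf = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_cmtf)


def restrict_tensor(tensor: tt.FeatureTensor, label: str) -> tt.FeatureTensor:
    keep = [i for i, c in enumerate(tensor.sample_classes) if c == label]
    return tt.FeatureTensor(
        values=tensor.values[:, keep, :],
        feature_names=tensor.feature_names,
        sample_ids=[tensor.sample_ids[i] for i in keep],
        times=tensor.times,
        sample_classes=[label] * len(keep),
    )


def restrict_matrix(matrix: tt.FeatureMatrix, label: str) -> tt.FeatureMatrix:
    keep = [i for i, c in enumerate(matrix.sample_classes) if c == label]
    return tt.FeatureMatrix(
        values=matrix.values[:, keep],
        feature_names=matrix.feature_names,
        sample_ids=[matrix.sample_ids[i] for i in keep],
        sample_classes=[label] * len(keep),
    )


def main() -> None:
    warnings.filterwarnings("ignore")
    tensor = _cmtf._cp_invitro.load_invitro_tensor()
    matrix = _cmtf.load_histology_matrix(tensor.feature_names)

    summary = {}
    for label in ("cancer", "healthy"):
        tsub = restrict_tensor(tensor, label)
        msub = restrict_matrix(matrix, label)
        r = tt.cluster_invitro_vs_histology(tsub, msub)
        n = len(r.source_labels)
        print(
            f"{label}: first two SVD components explain "
            f"{100 * r.explained_variance_first_two:.1f}% of variance; "
            f"in vitro vs histology misclassified "
            f"{r.separation.best_misclassified}/{n}"
        )
        summary[label] = {
            "explained_variance_first_two_pct": 100 * r.explained_variance_first_two,
            "misclassified": r.separation.best_misclassified,
            "n_columns": n,
        }

    # cumulative variance curves of the standardized per-class source matrices
    mats = {}
    for label in ("cancer", "healthy"):
        tsub = restrict_tensor(tensor, label)
        msub = restrict_matrix(matrix, label)
        from tissuetensor.analysis import fit_transform_params

        iv = matricize(tsub.values, 0)
        mats[f"invitro_{label}"] = fit_transform_params(iv, drop_constant=True).apply(iv)
        hv = msub.values
        mats[f"histology_{label}"] = fit_transform_params(hv, drop_constant=True).apply(hv)
    curves, merges = tt.cumulative_variance_curves(mats, n_components=20)
    curves.to_csv(RESULTS / "variance_curves.csv")
    for (a, b), k in sorted(merges.items()):
        tag = f"component {k}" if k else "never (within 0.02)"
        print(f"curves {a} vs {b}: merge from {tag}")
    summary["merge_components"] = {f"{a}|{b}": k for (a, b), k in merges.items()}
    (RESULTS / "cluster_sources_summary.json").write_text(
        json.dumps(summary, indent=1, default=float)
    )
    print("-> results/variance_curves.csv, results/cluster_sources_summary.json")


if __name__ == "__main__":
    main()
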