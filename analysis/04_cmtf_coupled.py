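#!/usr/bin/env python
"""Coupled analysis: CMTF of the in vitro tensor and the histology matrix.

Couples the two sources through their shared features mode and fits CMTF
models at ranks 1 and 2, checking for degenerate (negatively correlated)
component pairs.  For the selected model, healthy-vs-cancer separation is
quantified in both sample modes and the common features-mode component is
ranked for influential features.

Run:  python analysis/04_cmtf_coupled.py [--seed 1]
"""

import argparse
import importlib.util
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

import tissuetensor as tt
from tissuetensor import io as tio
from tissuetensor.synthetic import substream_seed

RESULTS = Path(__file__).resolve().parent.parent / "results"

_spec = importlib.util.spec_from_file_location(
    "cp_invitro", Path(__file__).with_name("03_cp_invitro.py")
)
_cp_invitro = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_cp_invitro)


def load_histology_matrix(feature_names: list[str]) -> tt.FeatureMatrix:
    table = tio.read_feature_table(RESULTS / "histology_features.csv")
    missing = [c for c in feature_names if c not in table.columns]
    if missing:
        raise ValueError(f"histology table lacks features {missing}")
    values = table[feature_names].to_numpy(dtype=float).T
    return tt.FeatureMatrix(
        values=values,
        feature_names=feature_names,
        sample_ids=table["sample_id"].tolist(),
        sample_classes=table["label"].tolist(),
    )


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    warnings.filterwarnings("ignore")

    tensor = _cp_invitro.load_invitro_tensor()
    matrix = load_histology_matrix(tensor.feature_names)
    print(f"tensor {tensor.shape} coupled with matrix {matrix.values.shape} "
          "in the features mode")

    results = {}
    for R in (1, 2):
        r = tt.analyze_coupled(
            tensor, matrix, rank=R, seed=substream_seed(args.seed, f"cmtf-r{R}")
        )
        degen = tt.degenerate_pairs([r.model.A, r.model.B, r.model.C])
        results[R] = (r, degen)
        print(f"  R={R}: objective {r.model.objective:10.1f}, "
              f"degenerate pairs: {len(degen)}")
    # keep the largest non-degenerate model
    chosen = max((R for R, (_, d) in results.items() if not d), default=1)
    r, _ = results[chosen]
    print(f"chosen rank: {chosen} (largest model without degenerate components)")

    null_b = tt.permutation_null(
        r.model.B, tensor.sample_classes, seed=substream_seed(args.seed, "null-b"))
    null_d = tt.permutation_null(
        r.model.D, matrix.sample_classes, seed=substream_seed(args.seed, "null-d"))
    print(
        f"in vitro mode (B): misclassifies "
        f"{r.separation_invitro.best_misclassified}/{len(tensor.sample_ids)} "
        f"(null 5th pct {np.percentile(null_b, 5):.0f})"
    )
    print(
        f"histology mode (D): misclassifies "
        f"{r.separation_histology.best_misclassified}/{len(matrix.sample_ids)} "
        f"(null 5th pct {np.percentile(null_d, 5):.0f})"
    )
    print("features captured by the common component:")
    print(r.influential_features.to_string(index=False))

    tio.write_cmtf_model(r.model, RESULTS / "cmtf_model.h5")
    summary = {
        "chosen_rank": chosen,
        "objective": r.model.objective,
        "misclassified_invitro": r.separation_invitro.misclassified,
        "misclassified_histology": r.separation_histology.misclassified,
        "null_5th_pct_invitro": float(np.percentile(null_b, 5)),
        "null_5th_pct_histology": float(np.percentile(null_d, 5)),
        "influential_features": r.influential_features.to_dict("records"),
        "degenerate_pairs_at_rank_2": [
            {"i": i, "j": j, "congruence": c} for i, j, c in results[2][1]
        ],
    }
    (RESULTS / "cmtf_summary.json").write_text(json.dumps(summary, indent=1, default=float))
    print("-> results/cmtf_model.h5, results/cmtf_summary.json")


if __name__ == "__main__":
    main()
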