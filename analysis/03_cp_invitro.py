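#!/usr/bin/env python
"""Three-way analysis of the in vitro tensor: CP vs matricized SVD.

Assembles the (features x samples x time) tensor from the feature table of
02, applies the default exclusion list, sweeps the CP rank over 1..4 with
the core consistency diagnostic, quantifies healthy-vs-cancer separation on
the samples-mode components of the chosen model, ranks the influential
features, and contrasts with a plain SVD of the tensor matricized in the
features mode (two-way analysis across all times).

Run:  python analysis/03_cp_invitro.py [--seed 1]
"""

import argparse
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

import tissuetensor as tt
from tissuetensor import io as tio
from tissuetensor.analysis import fit_transform_params
from tissuetensor.synthetic import substream_seed

RESULTS = Path(__file__).resolve().parent.parent / "results"


def load_invitro_tensor() -> tt.FeatureTensor:
    table = tio.read_feature_table(RESULTS / "invitro_features.csv")
    # drop feature columns that are undefined (non-finite) for any graph
    feat_cols = [c for c in table.columns if c in tt.FEATURE_NAMES]
    bad = [c for c in feat_cols if not np.isfinite(table[c]).all()]
    if bad:
        print(f"dropping {len(bad)} feature(s) undefined on some graphs: {bad}")
    return tt.assemble_tensor(
        table.drop(columns=bad), excluded=tt.DEFAULT_EXCLUSIONS
    )


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    warnings.filterwarnings("ignore")

    tensor = load_invitro_tensor()
    print(f"tensor: {tensor.shape} (features x samples x time)")
    Z, _ = tt.preprocess(tensor)

    sweep = {}
    for R in (1, 2, 3, 4):
        m = tt.cp_als(Z, R, seed=substream_seed(args.seed, f"cp-r{R}"))
        sweep[R] = {"fit_pct": m.fit, "core_consistency": tt.core_consistency(Z, m)}
        print(f"  R={R}: fit {m.fit:5.1f}%  core consistency {sweep[R]['core_consistency']:8.1f}")
    # choose the largest rank whose core consistency stays high
    chosen = max((R for R in sweep if sweep[R]["core_consistency"] > 90), default=1)
    print(f"chosen rank: {chosen} (core consistency diagnostic)")

    r = tt.analyze_invitro(tensor, rank=chosen, seed=substream_seed(args.seed, "cp-final"))
    null = tt.permutation_null(
        r.model.factors[1], tensor.sample_classes, seed=substream_seed(args.seed, "null")
    )
    print(
        f"samples-mode separation: component {r.separation.best_component + 1} "
        f"misclassifies {r.separation.best_misclassified}/{len(tensor.sample_ids)} "
        f"(permutation null 5th pct: {np.percentile(null, 5):.0f})"
    )
    print("influential features (|coefficient| in separating component):")
    print(r.influential_features.to_string(index=False))

    # two-way comparison: SVD of the matricized tensor (features x samples-time)
    M = tt.matricize(Z, 0)
    svd = tt.svd_lowrank(M, k=2)
    # per (sample, time) scores labeled by the sample's class
    st_classes = [c for c in tensor.sample_classes for _ in tensor.times]
    sep2 = tt.separation_score(svd.scores(), st_classes)
    print(
        f"two-way SVD across all times: best component misclassifies "
        f"{sep2.best_misclassified}/{len(st_classes)} sample-time points "
        f"(per-time-point separation is harder than three-way)"
    )

    scores = pd.DataFrame(
        r.separation.scores,
        columns=[f"component_{i+1}" for i in range(r.model.rank)],
    )
    scores.insert(0, "sample_id", tensor.sample_ids)
    scores.insert(1, "label", tensor.sample_classes)
    scores.to_csv(RESULTS / "cp_invitro_scores.csv", index=False)
    summary = {
        "tensor_shape": list(tensor.shape),
        "rank_sweep": sweep,
        "chosen_rank": chosen,
        "fit_pct": r.model.fit,
        "best_component": r.separation.best_component + 1,
        "misclassified": r.separation.misclassified,
        "permutation_null_5th_pct": float(np.percentile(null, 5)),
        "influential_features": r.influential_features.to_dict("records"),
        "two_way_svd_misclassified": sep2.best_misclassified,
        "two_way_n_sample_time_points": len(st_classes),
    }
    (RESULTS / "cp_invitro_summary.json").write_text(json.dumps(summary, indent=1, default=float))
    print("-> results/cp_invitro_scores.csv, results/cp_invitro_summary.json")


if __name__ == "__main__":
    main()
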