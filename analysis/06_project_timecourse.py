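#!/usr/bin/env python
"""Does the culture drift toward native-tissue organization over the week?

Computes the SVD of the cancerous histology samples (after centering and
scaling by the histology statistics), projects every cancerous in vitro
sample at every time point onto the first two histology singular vectors,
and tracks the mean distance to the histology score centroid per time point.
An interior minimum would indicate a "peak accuracy" time at which the
culture best resembles the native tissue.

Run:  python analysis/06_project_timecourse.py
"""

import importlib.util
import json
import warnings
from pathlib import Path

import tissuetensor as tt

RESULTS = Path(__file__).resolve().parent.parent / "results"

_spec = importlib.util.spec_from_file_location(
    "cluster_sources", Path(__file__).with_name("05_cluster_sources.py")
)
_cluster = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_cluster)


def main() -> None:
    warnings.filterwarnings("ignore")
    tensor = _cluster._cmtf._cp_invitro.load_invitro_tensor()
    matrix = _cluster._cmtf.load_histology_matrix(tensor.feature_names)
    tsub = _cluster.restrict_tensor(tensor, "cancer")
    msub = _cluster.restrict_matrix(matrix, "cancer")

    r = tt.project_timecourse(msub, tsub)
    r.coordinates.to_csv(RESULTS / "timecourse_projection.csv", index=False)
    print("mean distance to histology centroid per time point:")
    for t, d in r.distances.items():
        print(f"  t = {t:5.0f} h : {d:7.2f}")
    tmin = float(r.distances.idxmin())
    interior = tmin not in (tsub.times[0], tsub.times[-1])
    print(
        f"closest approach at t = {tmin:.0f} h "
        f"({'interior' if interior else 'boundary'} time point)"
    )
    summary = {
        "distances": {str(t): float(d) for t, d in r.distances.items()},
        "closest_time_h": tmin,
        "interior_minimum": interior,
    }
    (RESULTS / "timecourse_projection_summary.json").write_text(
        json.dumps(summary, indent=1)
    )
    print("-> results/timecourse_projection.csv, "
          "results/timecourse_projection_summary.json")


if __name__ == "__main__":
    main()
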