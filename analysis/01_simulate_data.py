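#!/usr/bin/env python
"""Simulate the study's two data sources with known class structure.

Generates (i) an in vitro time course -- 5 gels per class sampled at the 11
fixation times over one week, denser and more clumped for the cancerous
class -- and (ii) a synthetic "histology" set of 12 single-time point
patterns per class over the same field.  Writes both as point-pattern CSVs
under results/.

Run:  python analysis/01_simulate_data.py [--seed 1]
"""

import argparse
from pathlib import Path

import tissuetensor as tt
from tissuetensor import io as tio
from tissuetensor.synthetic import substream_seed

RESULTS = Path(__file__).resolve().parent.parent / "results"
N_HISTOLOGY_PER_CLASS = 12


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    invitro = []
    for label in ("healthy", "cancer"):
        invitro += tt.simulate_timecourse(
            tt.DEFAULT_CLASS_PARAMS[label], label=label, drift=0.5,
            seed=substream_seed(args.seed, f"invitro-{label}"),
        )
    tio.write_point_patterns(invitro, RESULTS / "invitro_points.csv")

    histology = []
    for label in ("healthy", "cancer"):
        streams = substream_seed(args.seed, f"hist-{label}").spawn(N_HISTOLOGY_PER_CLASS)
        for i, s in enumerate(streams):
            p = tt.simulate_point_pattern(
                tt.DEFAULT_CLASS_PARAMS[label], label=label, seed=s,
                sample_id=f"{label}_hist{i:02d}",
            )
            histology.append(p)
    tio.write_point_patterns(histology, RESULTS / "histology_points.csv")

    n_iv = len(invitro)
    print(f"in vitro: {n_iv} patterns ({n_iv // 11} samples x 11 time points), "
          f"median counts healthy/cancer: "
          f"{sorted(p.n_points for p in invitro if p.label == 'healthy')[len(invitro)//4]}"
          f"/{sorted(p.n_points for p in invitro if p.label == 'cancer')[len(invitro)//4]}")
    print(f"histology: {len(histology)} patterns "
          f"({N_HISTOLOGY_PER_CLASS} per class) -> results/")


if __name__ == "__main__":
    main()
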