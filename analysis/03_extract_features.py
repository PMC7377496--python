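#!/usr/bin/env python
"""Extract the 201-feature vector for every segmented step.

Recomputes segmentation from the saved cohort (windows are needed, not just
timings) and writes the steps x 201 feature matrix with subject, label and
recording metadata columns.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import gaitpd as g
from gaitpd.synthetic import read_recording


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/feature_matrix.csv"))
    args = ap.parse_args()

    steps = []
    for csv_path in sorted(args.cohort.glob("*_r*.csv")):
        rec, _ = read_recording(csv_path)
        steps.extend(g.segment_recording(g.preprocess(rec)))
    registry = g.default_registry()
    fm = g.build_matrix(steps, registry)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    fm.to_csv(args.out)
    registry.to_json(args.out.with_name("feature_registry.json"))

    print(f"feature matrix: {fm.n_steps} steps x {len(fm.feature_names)} features")
    print(f"labels: {int(fm.labels.sum())} PD steps / "
          f"{int((1 - fm.labels).sum())} control steps")
    print(f"-> {args.out}")


if __name__ == "__main__":
    main()
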