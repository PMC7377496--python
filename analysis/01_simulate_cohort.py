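#!/usr/bin/env python
"""Simulate the balanced walking-test cohort and save it for later stages.

Generates 29 PD + 29 control subjects (waist-IMU, nominal 100 Hz, ~20-step
walks with standing idle at both ends), writes each recording as CSV with a
JSON ground-truth sidecar, and prints the cohort summary.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import gaitpd as g
from gaitpd.synthetic import write_recording


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n-per-group", type=int, default=29)
    ap.add_argument("--recordings-per-subject", type=int, default=2)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    recs, meta = g.simulate_cohort(n_per_group=args.n_per_group,
                                   recordings_per_subject=args.recordings_per_subject,
                                   seed=args.seed)
    args.out.mkdir(parents=True, exist_ok=True)
    for sim in recs:
        write_recording(sim, args.out / f"{sim.recording.recording_id}.csv")
    meta.to_csv(args.out / "subjects.csv", index=False)

    print(f"subjects: {len(meta)}  ({(meta.group == 'PD').sum()} PD / "
          f"{(meta.group == 'control').sum()} control)")
    print(f"recordings: {len(recs)}")
    print(f"true steps: {meta.n_true_steps.sum()} "
          f"(per subject {meta.n_true_steps.min()}-{meta.n_true_steps.max()})")
    print(f"written to {args.out}/")


if __name__ == "__main__":
    main()
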