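#!/usr/bin/env python
"""Preprocess and segment the saved cohort into individual steps.

Each recording is interpolated to a uniform 100 Hz grid, low-pass filtered
(4th-order Butterworth, 20 Hz, zero-phase), its walking span located via the
wavelet activity envelope, and steps cut as fixed windows anchored at the
heel-strike troughs.  Writes a per-step timing table and reports how well
detection recovered the generator's ground-truth events.
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import gaitpd as g
from gaitpd.synthetic import read_recording


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/steps.csv"))
    args = ap.parse_args()

    rows, n_true, n_hit = [], 0, 0
    for csv_path in sorted(args.cohort.glob("*_r*.csv")):
        rec, truth = read_recording(csv_path)
        uni = g.preprocess(rec)
        steps = g.segment_recording(uni)
        det_t = uni.t0 + np.array([s.timing.heel_strike_idx for s in steps]) / uni.fs
        if truth:
            true_hs = np.array(truth["heel_strikes"])
            n_true += len(true_hs)
            n_hit += sum(np.any(np.abs(det_t - hs) < 0.05) for hs in true_hs)
        for s in steps:
            rows.append(dict(recording_id=s.recording_id, subject_id=s.subject_id,
                             group=s.group, step_index=s.step_index,
                             heel_strike_t=uni.t0 + s.timing.heel_strike_idx / uni.fs,
                             A_i=s.timing.A_i, B_i=s.timing.B_i,
                             W=s.window_length))
    table = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)

    print(f"segmented {table.recording_id.nunique()} recordings "
          f"-> {len(table)} steps")
    if n_true:
        print(f"heel-strike recall within 50 ms: {100 * n_hit / n_true:.1f}% "
              f"({n_hit}/{n_true})")
    print(f"window length W: {table.W.min()}-{table.W.max()} samples; "
          f"mean step time {(table.A_i + table.B_i).mean():.3f} s")
    print(f"step table -> {args.out}")


if __name__ == "__main__":
    main()
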