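#!/usr/bin/env python
"""Nine-classifier LOSO evaluation, majority voting and statistical comparison.

Classifies every step with the full bank (kNN k=49, RF with 11 voting
repetitions, ...) on the mRMR-selected features under leave-one-subject-out
cross-validation, aggregates subjects by majority vote, prints step- and
subject-level accuracy/sensitivity/specificity with confusion counts, and
compares classifiers with Cochran's Q plus pairwise Dunn post-hoc tests.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import gaitpd as g
from gaitpd.evaluate import correctness_matrix


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--features", type=Path, default=Path("results/feature_matrix.csv"))
    ap.add_argument("--selection", type=Path, default=Path("results/selection/mrmr_15.json"))
    ap.add_argument("--out", type=Path, default=Path("results/evaluation"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    fm = g.FeatureMatrix.from_csv(args.features)
    selected = g.SelectionResult.from_json(args.selection).selected
    bank = g.default_bank(seed=args.seed)
    preds = g.run_loso(fm.subset(selected), bank)

    rows = []
    for clf, grp in preds.groupby("classifier"):
        ev = g.summarize(grp)
        rows.append(ev.to_dict())
        print(f"{clf:16s} step acc {100 * ev.step_accuracy:5.1f}%  "
              f"subject acc {100 * ev.subject_accuracy:5.1f}% "
              f"(sens {100 * ev.subject_sensitivity:.1f}% "
              f"spec {100 * ev.subject_specificity:.1f}%; "
              f"TP {ev.tp} TN {ev.tn} FP {ev.fp} FN {ev.fn})")
    metrics = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    metrics.to_csv(args.out / "metrics.csv", index=False)
    preds.to_csv(args.out / "step_predictions.csv", index=False)

    comp = g.posthoc_pairwise(correctness_matrix(preds, level="step"))
    comp.pairwise.to_csv(args.out / "posthoc_pairwise.csv")
    print(f"\nCochran's Q = {comp.cochran_Q:.1f}, p = {comp.cochran_p:.3g}")
    sim = comp.similar_pairs()
    print(f"statistically similar pairs (p >= 0.01): {sim if sim else 'none'}")
    print(f"tables -> {args.out}/")


if __name__ == "__main__":
    main()
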