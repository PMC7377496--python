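#!/usr/bin/env python
"""Compare feature-selection strategies on the extracted step features.

Runs (a) the mRMR size sweep (5..100 in steps of 5 by default) scored by
LOSO step accuracy with SVM, logistic regression and LDA; (b) mRMR at the
final size of 15; (c) sequential forward selection per classifier; and
(d) the random forest's own top-20 importance ranking.  Writes the sweep
table and the selected sets as JSON.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import gaitpd as g
from gaitpd.classify import ClassifierSpec


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--features", type=Path, default=Path("results/feature_matrix.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/selection"))
    ap.add_argument("--sweep-max", type=int, default=100,
                    help="largest mRMR size in the sweep")
    ap.add_argument("--sfs-classifiers", nargs="*", default=["lda", "knn"],
                    help="classifiers to run forward selection for")
    ap.add_argument("--knn-k", type=int, default=49)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    fm = g.FeatureMatrix.from_csv(args.features)
    args.out.mkdir(parents=True, exist_ok=True)

    sizes = list(range(5, args.sweep_max + 1, 5))
    sweep_specs = [ClassifierSpec("svm"), ClassifierSpec("logreg"),
                   ClassifierSpec("lda")]
    sweep = g.mrmr_sweep(fm, sizes, sweep_specs)
    sweep.to_csv(args.out / "mrmr_sweep.csv", index=False)
    best = sweep.loc[sweep.groupby("classifier")["accuracy"].idxmax()]
    print("mRMR sweep best sizes:")
    for _, r in best.iterrows():
        print(f"  {r.classifier:8s} size {int(r['size']):3d} "
              f"accuracy {100 * r.accuracy:.1f}%")

    res = g.mrmr_rank(fm, 15)
    res.to_json(args.out / "mrmr_15.json")
    print(f"mRMR final set (15): {', '.join(res.selected[:5])} ...")

    for name in args.sfs_classifiers:
        params = {"k": args.knn_k} if name == "knn" else {}
        sfs = g.sequential_select(fm, ClassifierSpec(name, params=params),
                                  direction="forward", seed=args.seed)
        sfs.to_json(args.out / f"sfs_{name}.json")
        print(f"SFS[{name}]: {len(sfs.selected)} features, "
              f"final CV error {sfs.criterion_trace[-1]:.3f}")

    rf = g.rf_importance_top(fm, n=20, seed=args.seed)
    rf.to_json(args.out / "rf_top20.json")
    print(f"RF importance top-20 written -> {args.out}/")


if __name__ == "__main__":
    main()
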