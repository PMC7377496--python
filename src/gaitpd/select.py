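"""Feature selection: mRMR ranking, sequential wrappers, RF importance.

mRMR greedily ranks features by mutual information with the class label
(relevance) penalized by the mean mutual information with features already
chosen (redundancy); the difference criterion (MID) is used by default.
Mutual information between continuous features is estimated by a plug-in
estimator after equal-frequency discretization (8 bins by default).

The sequential wrappers grow (SFS) or shrink (SBS) a feature set driven by
the subject-grouped cross-validated misclassification rate of a given
classifier, stopping when no single move strictly improves the criterion.
Because wrapper cost grows quadratically with the feature count, SBS
accepts an evaluation budget.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GroupKFold

from .classify import ClassifierSpec, build_estimator
from .features import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Ordered selected features plus the per-move criterion trace."""

    method: str                       # {"mRMR", "SFS", "SBS", "RF_importance"}
    selected: List[str]
    criterion_trace: List[float]
    classifier_name: Optional[str] = None

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected features must be unique")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            dict(method=self.method, selected=self.selected,
                 criterion_trace=self.criterion_trace,
                 classifier_name=self.classifier_name), indent=1))

    @classmethod
    def from_json(cls, path) -> "SelectionResult":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# mutual information on discretized features

def discretize(x: np.ndarray, n_bins: int = 8) -> np.ndarray:
    """Equal-frequency binning into at most ``n_bins`` integer codes."""
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(edges)  # ties can collapse bins
    return np.searchsorted(edges, x, side="right")


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (nats) between two integer-coded arrays."""
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    n = a.size
    ka, kb = a.max() + 1, b.max() + 1
    joint = np.bincount(a * kb + b, minlength=ka * kb).reshape(ka, kb) / n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / np.outer(pa, pb)[nz])).sum())


def mrmr_rank(fm: FeatureMatrix, n_features: int, n_bins: int = 8,
              criterion: str = "MID") -> SelectionResult:
    """Greedy mRMR ranking of ``n_features`` features.

    The first pick maximizes relevance MI(f, label); each later pick
    maximizes relevance minus (MID) or divided by (MIQ) the mean redundancy
    MI with already-selected features.  Ties break toward the lower feature
    index, so the ranking is deterministic and extending n preserves the
    greedy prefix.
    """
    p = len(fm.feature_names)
    if not (1 <= n_features <= p):
        raise ValueError(f"n_features must be in [1, {p}]")
    if criterion not in ("MID", "MIQ"):
        raise ValueError("criterion must be 'MID' or 'MIQ'")
    if not np.all(np.isfinite(fm.values)):
        raise ValueError("feature matrix contains non-finite values")

    codes = np.column_stack([discretize(fm.values[:, j], n_bins) for j in range(p)])
    y = fm.labels
    relevance = np.array([mutual_information(codes[:, j], y) for j in range(p)])

    selected: List[int] = []
    trace: List[float] = []
    red_sum = np.zeros(p)
    pairwise_cache: Dict[Tuple[int, int], float] = {}
    remaining = np.ones(p, dtype=bool)
    for _ in range(n_features):
        if selected:
            mean_red = red_sum / len(selected)
            if criterion == "MID":
                score = relevance - mean_red
            else:
                score = relevance / (mean_red + 1e-12)
        else:
            score = relevance.copy()
        score[~remaining] = -np.inf
        best = int(np.argmax(score))  # argmax takes the first (lowest index) tie
        selected.append(best)
        trace.append(float(score[best]))
        remaining[best] = False
        for j in np.flatnonzero(remaining):
            key = (min(best, j), max(best, j))
            if key not in pairwise_cache:
                pairwise_cache[key] = mutual_information(codes[:, best], codes[:, j])
            red_sum[j] += pairwise_cache[key]
    return SelectionResult(method="mRMR",
                           selected=[fm.feature_names[j] for j in selected],
                           criterion_trace=trace)


def mrmr_sweep(fm: FeatureMatrix, sizes: Sequence[int],
               specs: Sequence[ClassifierSpec], n_bins: int = 8) -> pd.DataFrame:
    """LOSO step accuracy for mRMR subsets of several sizes and classifiers.

    Returns a tidy table (size, classifier, accuracy).  Sizes like
    5..100 in steps of 5 trace how accuracy first rises then falls as noise
    features accumulate.
    """
    from .evaluate import run_loso, summarize  # local import avoids cycle

    if len(sizes) == 0:
        raise ValueError("sizes must be non-empty")
    ranking = mrmr_rank(fm, max(sizes), n_bins=n_bins)
    rows = []
    for size in sizes:
        names = ranking.selected[:size]
        preds = run_loso(fm.subset(names), specs)
        for clf, g in preds.groupby("classifier"):
            rows.append(dict(size=size, classifier=clf,
                             accuracy=summarize(g).step_accuracy))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sequential wrappers

def _cv_error(fm: FeatureMatrix, feat_idx: Sequence[int], spec: ClassifierSpec,
              n_folds: int, seed: int) -> float:
    """Subject-grouped K-fold misclassification rate on a feature subset."""
    x = fm.values[:, list(feat_idx)]
    y = fm.labels
    groups = fm.subject_ids
    n_folds = min(n_folds, np.unique(groups).size)
    cv = GroupKFold(n_splits=n_folds)
    errors = 0
    for train, test in cv.split(x, y, groups):
        if np.unique(y[train]).size < 2:
            return 1.0  # degenerate fold: treat subset as uninformative
        est = build_estimator(spec, seed=seed)
        est.fit(x[train], y[train])
        errors += int(np.sum(est.predict(x[test]) != y[test]))
    return errors / len(y)


def sequential_select(fm: FeatureMatrix, spec: ClassifierSpec,
                      direction: str = "forward", n_folds: int = 10,
                      seed: int = 0, max_features: Optional[int] = None,
                      max_evals: Optional[int] = None) -> SelectionResult:
    """Sequential forward (SFS) or backward (SBS) wrapper selection.

    Forward starts empty and adds the feature that most reduces the
    cross-validated misclassification rate; backward starts with all
    features and removes while some removal strictly improves it.  Both
    stop at the first round with no strictly improving move (or at
    ``max_features`` / the ``max_evals`` evaluation budget).  The criterion
    trace records the error after each accepted move.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    p = len(fm.feature_names)
    evals = 0

    def criterion(idx: Sequence[int]) -> float:
        nonlocal evals
        evals += 1
        try:
            return _cv_error(fm, idx, spec, n_folds, seed)
        except Exception as exc:  # candidate set broke the classifier: skip it
            warnings.warn(f"candidate {idx} failed: {exc}")
            return np.inf

    trace: List[float] = []
    if direction == "forward":
        current: List[int] = []
        best_err = np.inf
        limit = max_features or p
        while len(current) < limit:
            cand_errs = []
            for j in range(p):
                if j in current:
                    continue
                if max_evals is not None and evals >= max_evals:
                    break
                cand_errs.append((criterion(current + [j]), j))
            if not cand_errs:
                break
            err, j = min(cand_errs)
            if err >= best_err:
                break
            current.append(j)
            best_err = err
            trace.append(err)
            if max_evals is not None and evals >= max_evals:
                break
        method = "SFS"
    else:
        current = list(range(p))
        best_err = criterion(current)
        trace.append(best_err)
        improved = True
        while improved and len(current) > 1:
            improved = False
            cand_errs = []
            for j in list(current):
                if max_evals is not None and evals >= max_evals:
                    break
                subset = [i for i in current if i != j]
                cand_errs.append((criterion(subset), j))
            if not cand_errs:
                break
            err, j = min(cand_errs)
            if err < best_err:
                current.remove(j)
                best_err = err
                trace.append(err)
                improved = True
            if max_evals is not None and evals >= max_evals:
                break
        method = "SBS"

    if not current:
        raise ValueError("selection terminated with an empty feature set")
    return SelectionResult(method=method,
                           selected=[fm.feature_names[j] for j in current],
                           criterion_trace=trace,
                           classifier_name=spec.name)


def rf_importance_top(fm: FeatureMatrix, n: int = 20, n_trees: int = 100,
                      seed: int = 0) -> SelectionResult:
    """Top-``n`` features by random-forest impurity importance.

    Mirrors the two-round forest protocol: fit once on all features, keep
    the ``n`` most important, refit downstream on those.
    """
    p = len(fm.feature_names)
    if not (1 <= n <= p):
        raise ValueError(f"n must be in [1, {p}]")
    rf = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                random_state=seed)
    rf.fit(fm.values, fm.labels)
    order = np.argsort(-rf.feature_importances_, kind="stable")[:n]
    return SelectionResult(method="RF_importance",
                           selected=[fm.feature_names[j] for j in order],
                           criterion_trace=[float(rf.feature_importances_[j])
                                            for j in order],
                           classifier_name="random_forest")
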