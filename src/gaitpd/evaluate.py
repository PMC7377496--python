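"""Leave-one-subject-out evaluation, majority voting and classifier comparison.

Step-level metrics are pooled over all LOSO folds (accuracy = correctly
classified steps / all steps; sensitivity over true-PD steps, specificity
over true-control steps).  Subject-level calls are the majority vote of the
subject's step predictions (> 50% PD steps -> PD; an exact tie defaults to
PD, favouring sensitivity in a screening setting), yielding a subject
confusion matrix and the same three metrics plus the misclassification rate.

Classifier banks are compared with Cochran's Q on the items x classifiers
correctness matrix, followed by pairwise post-hoc tests (rank-based Dunn
z-tests with tie correction and Bonferroni adjustment by default; pairwise
McNemar available as an alternative backend).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .classify import ClassifierSpec, fit_predict, rf_repeated
from .features import FeatureMatrix

LABEL_NAMES = {1: "PD", 0: "control"}


def loso_folds(fm: FeatureMatrix) -> List[Tuple[np.ndarray, np.ndarray]]:
    """One fold per subject: test = that subject's steps, train = the rest.

    Folds are ordered by sorted subject id.  Fold construction uses only the
    subject-id metadata, never the feature values or labels.
    """
    subjects = np.unique(fm.subject_ids)
    if subjects.size < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    if np.unique(fm.labels).size < 2:
        raise ValueError("both classes must be present")
    folds = []
    for s in subjects:
        test = fm.subject_ids == s
        folds.append((np.flatnonzero(~test), np.flatnonzero(test)))
    return folds


def run_loso(fm: FeatureMatrix, specs: Sequence[ClassifierSpec],
             feature_names: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Pooled LOSO step predictions for every classifier in ``specs``.

    ``feature_names`` restricts the matrix to an already-selected subset
    (selection performed once on all steps — the protocol's default; use
    :func:`gaitpd.pipeline.run_pipeline` with ``nested_selection`` for
    per-fold re-selection).
    """
    if feature_names is not None:
        fm = fm.subset(feature_names)
    frames = []
    for fold_id, (train_idx, test_idx) in enumerate(loso_folds(fm)):
        train = fm.rows(train_idx)
        test = fm.rows(test_idx)
        for spec in specs:
            if spec.name == "random_forest" and spec.params.get("n_repeats", 1) > 1:
                frames.append(rf_repeated(spec, train, test, fold=fold_id))
            else:
                frames.append(fit_predict(spec, train, test, fold=fold_id))
    return pd.concat(frames, ignore_index=True)


def majority_vote(preds: pd.DataFrame, subject_id: Optional[str] = None,
                  tie: str = "PD") -> pd.DataFrame:
    """Subject-level calls from step predictions of ONE classifier.

    A subject is called PD when more than 50% of their steps are classified
    PD; an exact 50% tie resolves to ``tie`` ("PD" by default).  Returns a
    table (subject_id, y_true, y_pred, pd_fraction, n_steps); with
    ``subject_id`` given, only that subject's row.
    """
    if preds["classifier"].nunique() > 1:
        raise ValueError("majority_vote expects predictions of a single classifier")
    if subject_id is not None:
        preds = preds[preds["subject_id"] == subject_id]
        if preds.empty:
            raise ValueError(f"no predicted steps for subject {subject_id!r}")
    tie_label = {"PD": 1, "control": 0}[tie]
    rows = []
    for sid, g in preds.groupby("subject_id", sort=True):
        frac = g["y_pred"].mean()
        call = 1 if frac > 0.5 else 0 if frac < 0.5 else tie_label
        rows.append(dict(subject_id=sid, y_true=int(g["y_true"].iloc[0]),
                         y_pred=call, pd_fraction=float(frac), n_steps=len(g)))
    return pd.DataFrame(rows)


def _rates(y_true: np.ndarray, y_pred: np.ndarray) -> Tuple[float, float, float]:
    acc = float(np.mean(y_true == y_pred))
    pd_mask = y_true == 1
    sens = float(np.mean(y_pred[pd_mask] == 1)) if pd_mask.any() else float("nan")
    spec = float(np.mean(y_pred[~pd_mask] == 0)) if (~pd_mask).any() else float("nan")
    return acc, sens, spec


@dataclass
class EvaluationResult:
    """Step- and subject-level metrics for one classifier's LOSO predictions."""

    classifier: str
    step_accuracy: float
    step_sensitivity: float
    step_specificity: float
    subject_calls: pd.DataFrame
    subject_accuracy: float
    subject_sensitivity: float
    subject_specificity: float
    misclassification_rate: float
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n_subjects(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> Dict[str, float]:
        return {
            "classifier": self.classifier,
            "step_accuracy": self.step_accuracy,
            "step_sensitivity": self.step_sensitivity,
            "step_specificity": self.step_specificity,
            "subject_accuracy": self.subject_accuracy,
            "subject_sensitivity": self.subject_sensitivity,
            "subject_specificity": self.subject_specificity,
            "misclassification_rate": self.misclassification_rate,
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
        }


def summarize(preds: pd.DataFrame, tie: str = "PD") -> EvaluationResult:
    """Compute pooled step metrics and majority-vote subject metrics."""
    calls = majority_vote(preds, tie=tie)
    step_acc, step_sens, step_spec = _rates(preds["y_true"].to_numpy(),
                                            preds["y_pred"].to_numpy())
    yt = calls["y_true"].to_numpy()
    yp = calls["y_pred"].to_numpy()
    subj_acc, subj_sens, subj_spec = _rates(yt, yp)
    tp = int(np.sum((yt == 1) & (yp == 1)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    return EvaluationResult(
        classifier=str(preds["classifier"].iloc[0]),
        step_accuracy=step_acc, step_sensitivity=step_sens,
        step_specificity=step_spec, subject_calls=calls,
        subject_accuracy=subj_acc, subject_sensitivity=subj_sens,
        subject_specificity=subj_spec,
        misclassification_rate=1.0 - subj_acc,
        tp=tp, tn=tn, fp=fp, fn=fn)


def correctness_matrix(preds: pd.DataFrame, level: str = "step") -> pd.DataFrame:
    """items x classifiers binary matrix of correct (1) / wrong (0) outcomes.

    ``level="step"`` uses pooled step predictions (items = steps),
    ``level="subject"`` the majority-vote calls (items = subjects).
    """
    if level == "step":
        df = preds.copy()
        df["correct"] = (df["y_true"] == df["y_pred"]).astype(int)
        df["item"] = df.groupby("classifier").cumcount()
        wide = df.pivot(index="item", columns="classifier", values="correct")
    elif level == "subject":
        parts = {}
        for clf, g in preds.groupby("classifier"):
            calls = majority_vote(g)
            parts[clf] = pd.Series(
                (calls["y_true"] == calls["y_pred"]).astype(int).to_numpy(),
                index=calls["subject_id"])
        wide = pd.DataFrame(parts)
    else:
        raise ValueError("level must be 'step' or 'subject'")
    if wide.isna().any().any():
        raise ValueError("classifiers must cover identical items")
    return wide.astype(int)


def cochran_q(correctness) -> Tuple[float, float]:
    """Cochran's Q test across k matched classifiers on binary outcomes.

    Q = k (k-1) sum_j (C_j - N/k)^2 / (k sum_i R_i - sum_i R_i^2), compared
    with chi-square on k-1 degrees of freedom.  Rows with identical outcomes
    across classifiers contribute nothing; a fully degenerate matrix gives
    Q = 0, p = 1.
    """
    x = np.asarray(correctness, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 items and 2 classifiers")
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("correctness matrix must be binary")
    n, k = x.shape
    col = x.sum(axis=0)
    row = x.sum(axis=1)
    denom = k * row.sum() - (row ** 2).sum()
    if denom == 0:
        return 0.0, 1.0
    q = k * (k - 1) * ((col - col.mean()) ** 2).sum() / denom
    p = float(sps.chi2.sf(q, k - 1))
    return float(q), p


def _dunn_pairwise(x: np.ndarray, names: Sequence[str]) -> pd.DataFrame:
    """Rank-based Dunn z-tests between all column pairs, Bonferroni-adjusted."""
    n, k = x.shape
    total = n * k
    ranks = sps.rankdata(x.ravel()).reshape(n, k)
    mean_ranks = ranks.mean(axis=0)
    _, counts = np.unique(x.ravel(), return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (12.0 * (total - 1))
    var_term = total * (total + 1) / 12.0 - tie_term
    m = k * (k - 1) // 2
    pmat = pd.DataFrame(np.eye(k) * 0 + 1.0, index=names, columns=names)
    for i, j in combinations(range(k), 2):
        se = np.sqrt(var_term * (2.0 / n))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p = min(2.0 * sps.norm.sf(abs(z)) * m, 1.0)
        pmat.iloc[i, j] = pmat.iloc[j, i] = p
    return pmat


def _mcnemar_pairwise(x: np.ndarray, names: Sequence[str]) -> pd.DataFrame:
    """Pairwise McNemar tests (statsmodels), Bonferroni-adjusted."""
    n, k = x.shape
    m = k * (k - 1) // 2
    pmat = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for i, j in combinations(range(k), 2):
        a, b = x[:, i], x[:, j]
        table = [[np.sum((a == 1) & (b == 1)), np.sum((a == 1) & (b == 0))],
                 [np.sum((a == 0) & (b == 1)), np.sum((a == 0) & (b == 0))]]
        exact = (table[0][1] + table[1][0]) < 25
        res = _sm_mcnemar(table, exact=exact, correction=True)
        pmat.iloc[i, j] = pmat.iloc[j, i] = min(float(res.pvalue) * m, 1.0)
    return pmat


@dataclass
class ComparisonResult:
    """Cochran's Q omnibus plus pairwise post-hoc p-values."""

    cochran_Q: float
    cochran_p: float
    pairwise: pd.DataFrame
    alpha: float = 0.01
    method: str = "dunn"

    def similar_pairs(self) -> List[Tuple[str, str]]:
        """Pairs whose post-hoc p >= alpha (not distinguishable)."""
        out = []
        names = list(self.pairwise.columns)
        for i, j in combinations(range(len(names)), 2):
            if self.pairwise.iloc[i, j] >= self.alpha:
                out.append((names[i], names[j]))
        return out


def posthoc_pairwise(correctness, alpha: float = 0.01,
                     method: str = "dunn") -> ComparisonResult:
    """Omnibus Cochran's Q + pairwise post-hoc comparison of classifiers.

    ``method`` selects the pairwise backend: "dunn" (rank-based z-tests with
    tie correction) or "mcnemar".  P-values are Bonferroni-adjusted over the
    C(k, 2) pairs; pairs with p >= alpha are flagged as statistically
    similar.
    """
    df = pd.DataFrame(correctness)
    q, p = cochran_q(df.to_numpy())
    x = df.to_numpy(float)
    names = [str(c) for c in df.columns]
    if method == "dunn":
        pmat = _dunn_pairwise(x, names)
    elif method == "mcnemar":
        pmat = _mcnemar_pairwise(x, names)
    else:
        raise ValueError("method must be 'dunn' or 'mcnemar'")
    return ComparisonResult(cochran_Q=q, cochran_p=p, pairwise=pmat,
                            alpha=alpha, method=method)
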