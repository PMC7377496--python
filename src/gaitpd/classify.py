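"""The nine-classifier bank used for step-level PD/control classification.

The bank covers the common supervised baselines: a decision tree, an
RBF-kernel learner ("gaussian_kernel", random Fourier features + logistic
regression), LDA, a boosted-stump ensemble, kNN with k = 49 (odd, roughly
the square root of the training-set size, so step votes cannot tie),
logistic regression, Gaussian naive Bayes, a linear SVM, and a random
forest.  The random forest additionally supports the repeated-evaluation
protocol: an odd number of independently seeded forests vote on each test
step, so its stochastic variability is averaged out and ties are impossible.

Every estimator is wrapped in a pipeline whose standardization statistics
are fit on the training fold only — test-fold rows never touch the scaler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.kernel_approximation import RBFSampler
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix

CLASSIFIER_NAMES = (
    "tree", "gaussian_kernel", "lda", "ensemble", "knn",
    "logreg", "naive_bayes", "svm", "random_forest",
)

#: classifiers whose fit is invariant to training-row permutation
DETERMINISTIC_CLASSIFIERS = ("lda", "knn", "logreg", "naive_bayes", "svm")

#: prediction-table columns produced by fit_predict / run_loso
PREDICTION_COLUMNS = ("subject_id", "y_true", "y_pred", "classifier", "fold")


@dataclass(frozen=True)
class ClassifierSpec:
    """Name + hyperparameters + seed for one bank member."""

    name: str
    params: Dict[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}; "
                             f"choose from {CLASSIFIER_NAMES}")
        k = self.params.get("k")
        if self.name == "knn" and k is not None and k % 2 == 0:
            raise ValueError("knn k must be odd (binary vote must not tie)")
        reps = self.params.get("n_repeats")
        if reps is not None and reps % 2 == 0:
            raise ValueError("n_repeats must be odd (step votes must not tie)")


def default_bank(seed: int = 0, knn_k: int = 49,
                 rf_trees: int = 100, rf_repeats: int = 11) -> List[ClassifierSpec]:
    """The full nine-member bank at its default settings."""
    return [
        ClassifierSpec("tree", seed=seed),
        ClassifierSpec("gaussian_kernel", seed=seed),
        ClassifierSpec("lda", seed=seed),
        ClassifierSpec("ensemble", seed=seed),
        ClassifierSpec("knn", params={"k": knn_k}, seed=seed),
        ClassifierSpec("logreg", seed=seed),
        ClassifierSpec("naive_bayes", seed=seed),
        ClassifierSpec("svm", seed=seed),
        ClassifierSpec("random_forest",
                       params={"n_trees": rf_trees, "n_repeats": rf_repeats},
                       seed=seed),
    ]


def build_estimator(spec: ClassifierSpec, seed: Optional[int] = None) -> Pipeline:
    """Instantiate the scikit-learn pipeline for a spec (scaler + model)."""
    if seed is None:
        seed = spec.seed
    p = spec.params
    name = spec.name
    if name == "tree":
        model = DecisionTreeClassifier(random_state=seed)
    elif name == "gaussian_kernel":
        model = Pipeline([
            ("rbf", RBFSampler(gamma="scale", n_components=p.get("n_components", 300),
                               random_state=seed)),
            ("clf", LogisticRegression(max_iter=2000)),
        ])
    elif name == "lda":
        model = LinearDiscriminantAnalysis()
    elif name == "ensemble":
        model = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=p.get("n_rounds", 100), random_state=seed)
    elif name == "knn":
        model = KNeighborsClassifier(n_neighbors=p.get("k", 49))
    elif name == "logreg":
        model = LogisticRegression(max_iter=2000)
    elif name == "naive_bayes":
        model = GaussianNB()
    elif name == "svm":
        model = SVC(kernel=p.get("kernel", "linear"), C=p.get("C", 1.0),
                    random_state=seed)
    elif name == "random_forest":
        model = RandomForestClassifier(
            n_estimators=p.get("n_trees", 100), max_features="sqrt",
            random_state=seed)
    else:  # pragma: no cover - guarded by ClassifierSpec
        raise ValueError(name)
    return Pipeline([("scale", StandardScaler()), ("model", model)])


def _validate_split(train: FeatureMatrix, test: FeatureMatrix) -> None:
    if train.feature_names != test.feature_names:
        raise ValueError("train and test must share feature columns")
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training set must contain both classes")


def fit_predict(spec: ClassifierSpec, train: FeatureMatrix, test: FeatureMatrix,
                fold: int = 0) -> pd.DataFrame:
    """Train on ``train``, predict every ``test`` row.

    Returns a prediction table with columns :data:`PREDICTION_COLUMNS`.
    """
    _validate_split(train, test)
    if spec.name == "knn":
        k = spec.params.get("k", 49)
        if k > train.n_steps:
            raise ValueError(f"knn k={k} exceeds training size {train.n_steps}")
    est = build_estimator(spec)
    est.fit(train.values, train.labels)
    y_pred = est.predict(test.values)
    return pd.DataFrame({
        "subject_id": test.subject_ids,
        "y_true": test.labels,
        "y_pred": y_pred.astype(int),
        "classifier": spec.name,
        "fold": fold,
    })


def rf_repeated(spec: ClassifierSpec, train: FeatureMatrix, test: FeatureMatrix,
                n_repeats: Optional[int] = None, fold: int = 0) -> pd.DataFrame:
    """Random-forest evaluation repeated with distinct seeds, majority-voted.

    An odd repeat count guarantees no tied step votes; with
    ``n_repeats = 1`` this reduces exactly to :func:`fit_predict`.
    """
    if n_repeats is None:
        n_repeats = int(spec.params.get("n_repeats", 11))
    if n_repeats % 2 == 0:
        raise ValueError("n_repeats must be odd")
    _validate_split(train, test)
    seeds = np.random.SeedSequence(spec.seed).generate_state(n_repeats) % (2 ** 31)
    votes = np.zeros(test.n_steps, dtype=int)
    for s in seeds:
        est = build_estimator(spec, seed=int(s))
        est.fit(train.values, train.labels)
        votes += est.predict(test.values).astype(int)
    y_pred = (votes * 2 > n_repeats).astype(int)  # strict majority of odd count
    return pd.DataFrame({
        "subject_id": test.subject_ids,
        "y_true": test.labels,
        "y_pred": y_pred,
        "classifier": spec.name,
        "fold": fold,
        "pd_votes": votes,
        "n_repeats": n_repeats,
    })
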