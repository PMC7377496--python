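"""Feature-selection correctness against brute-force greedy oracles."""

from collections import Counter
from math import log

import numpy as np
import pytest
from sklearn.model_selection import GroupKFold

import gaitpd as g
from gaitpd.classify import ClassifierSpec, build_estimator
from gaitpd.features import FeatureMatrix
from gaitpd.select import discretize, mutual_information, mrmr_rank

from conftest import make_separable_fm


def _toy_fm(n=240, p=6, n_info=2, seed=0):
    """Small matrix with a few informative and several noise features."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    x = rng.standard_normal((n, p))
    for j in range(n_info):
        x[:, j] += (1.5 - 0.4 * j) * y
    subs = np.array([f"S{i % 12:02d}" for i in range(n)])
    return FeatureMatrix(x, [f"f{j}" for j in range(p)], subs, y,
                         np.char.add(subs, "_r"))


# ------------------------- independent oracles -----------------------------

def oracle_mi(a, b):
    """Plug-in MI via Counter-based frequency tables (pure Python)."""
    n = len(a)
    ca, cb = Counter(a), Counter(b)
    cab = Counter(zip(a, b))
    return sum((nab / n) * log((nab / n) / ((ca[i] / n) * (cb[j] / n)))
               for (i, j), nab in cab.items())


def oracle_mrmr(fm, k, n_bins=8):
    """Brute-force greedy MID ranking recomputing every term every round."""
    p = len(fm.feature_names)
    codes = [tuple(discretize(fm.values[:, j], n_bins)) for j in range(p)]
    y = tuple(fm.labels)
    chosen = []
    while len(chosen) < k:
        best, best_score = None, -np.inf
        for j in range(p):
            if j in chosen:
                continue
            rel = oracle_mi(codes[j], y)
            red = (sum(oracle_mi(codes[j], codes[s]) for s in chosen) / len(chosen)
                   if chosen else 0.0)
            score = rel - red
            if score > best_score + 1e-12:
                best, best_score = j, score
        chosen.append(best)
    return [fm.feature_names[j] for j in chosen]


def oracle_cv_error(fm, idx, spec, n_folds=10):
    x = fm.values[:, list(idx)]
    y = fm.labels
    n_folds = min(n_folds, np.unique(fm.subject_ids).size)
    errs = 0
    for tr, te in GroupKFold(n_splits=n_folds).split(x, y, fm.subject_ids):
        est = build_estimator(spec, seed=0)
        est.fit(x[tr], y[tr])
        errs += int(np.sum(est.predict(x[te]) != y[te]))
    return errs / len(y)


def oracle_sfs(fm, spec, n_folds=10):
    """Brute-force forward selection evaluating every candidate each round."""
    p = len(fm.feature_names)
    current, best = [], np.inf
    while True:
        cands = [(oracle_cv_error(fm, current + [j], spec, n_folds), j)
                 for j in range(p) if j not in current]
        if not cands:
            break
        err, j = min(cands)
        if err >= best:
            break
        current.append(j)
        best = err
    return [fm.feature_names[j] for j in current]


# ------------------------------- mRMR --------------------------------------

class TestMrmr:
    def test_matches_bruteforce_oracle(self):
        fm = _toy_fm()
        got = mrmr_rank(fm, 6).selected
        assert got == oracle_mrmr(fm, 6)

    def test_mi_estimator_matches_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 5, 300)
        b = (a + rng.integers(0, 3, 300)) % 5
        assert mutual_information(a, b) == pytest.approx(
            oracle_mi(tuple(a), tuple(b)), rel=1e-12)

    def test_duplicate_feature_penalized(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 300)
        f0 = y + 0.3 * rng.standard_normal(300)     # strongly informative
        f1 = f0.copy()                              # exact duplicate
        f2 = y + 1.2 * rng.standard_normal(300)     # weaker but non-redundant
        subs = np.array([f"S{i % 10}" for i in range(300)])
        fm = FeatureMatrix(np.column_stack([f0, f1, f2]), ["f0", "f1", "f2"],
                           subs, y, subs)
        sel = mrmr_rank(fm, 3).selected
        assert sel[0] == "f0"
        assert sel[1] == "f2"  # the duplicate is never chosen before f2

    def test_greedy_prefix_property(self):
        fm = _toy_fm(seed=5)
        assert mrmr_rank(fm, 6).selected[:4] == mrmr_rank(fm, 4).selected

    def test_requested_size_returned(self, small_cohort_fm):
        res = mrmr_rank(small_cohort_fm, 15)
        assert len(res.selected) == 15
        assert set(res.selected) <= set(small_cohort_fm.feature_names)


class TestSequential:
    def test_forward_matches_bruteforce_oracle(self):
        fm = _toy_fm(n=180, p=5, seed=3)
        spec = ClassifierSpec("lda")
        got = g.sequential_select(fm, spec, direction="forward").selected
        assert got == oracle_sfs(fm, spec)

    def test_perfect_feature_found_first(self, separable_fm):
        res = g.sequential_select(separable_fm, ClassifierSpec("lda"),
                                  direction="forward")
        assert res.selected[0] == "f0"

    def test_trace_non_increasing(self):
        fm = _toy_fm(seed=4)
        res = g.sequential_select(fm, ClassifierSpec("lda"), direction="forward")
        assert all(a >= b for a, b in zip(res.criterion_trace,
                                          res.criterion_trace[1:]))

    def test_backward_removes_noise(self):
        fm = make_separable_fm(n_subjects=10, n_noise=3, seed=7)
        res = g.sequential_select(fm, ClassifierSpec("lda"), direction="backward")
        assert "f0" in res.selected
        assert len(res.selected) <= 4

    def test_invalid_direction(self):
        with pytest.raises(ValueError):
            g.sequential_select(_toy_fm(), ClassifierSpec("lda"), direction="up")


class TestRfImportance:
    def test_exact_count(self, small_cohort_fm):
        assert len(g.rf_importance_top(small_cohort_fm, n=20).selected) == 20

    def test_full_set_is_identity(self):
        fm = _toy_fm()
        res = g.rf_importance_top(fm, n=6)
        assert sorted(res.selected) == sorted(fm.feature_names)

    def test_signal_features_recovered(self):
        hits = 0
        for seed in range(10):
            fm = _toy_fm(n=300, p=30, n_info=3, seed=seed)
            top = g.rf_importance_top(fm, n=20, seed=seed).selected
            hits += {"f0", "f1", "f2"} <= set(top)
        assert hits >= 9


class TestSweep:
    def test_single_size_consistent_with_rank(self):
        fm = _toy_fm()
        spec = ClassifierSpec("lda")
        tab = g.mrmr_sweep(fm, sizes=[4], specs=[spec])
        assert len(tab) == 1
        assert tab.iloc[0]["size"] == 4
        # same subset as a direct ranking + evaluation
        names = mrmr_rank(fm, 4).selected
        preds = g.run_loso(fm.subset(names), [spec])
        assert tab.iloc[0]["accuracy"] == pytest.approx(
            g.summarize(preds).step_accuracy)

    def test_row_count(self):
        fm = _toy_fm()
        tab = g.mrmr_sweep(fm, sizes=[2, 4, 6], specs=[ClassifierSpec("lda"),
                                                       ClassifierSpec("naive_bayes")])
        assert len(tab) == 6

    def test_accuracy_declines_with_noise_features(self):
        """Few informative + many noise features: small subsets beat large."""
        fm = _toy_fm(n=360, p=40, n_info=3, seed=9)
        tab = g.mrmr_sweep(fm, sizes=[3, 40], specs=[ClassifierSpec("lda")])
        acc = dict(zip(tab["size"], tab["accuracy"]))
        assert acc[3] >= acc[40]
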