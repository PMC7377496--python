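"""LOSO folds, majority voting, metric arithmetic and classifier comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.contingency_tables import cochrans_q as sm_cochrans_q
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

import gaitpd as g
from gaitpd.evaluate import correctness_matrix, majority_vote
from gaitpd.features import FeatureMatrix

from conftest import make_separable_fm


def _metadata_fm(n_subjects=58, steps=5, seed=0):
    """Random-feature matrix with realistic subject/label metadata."""
    rng = np.random.default_rng(seed)
    subs = np.repeat([f"S{i:03d}" for i in range(n_subjects)], steps)
    labels = np.repeat(np.arange(n_subjects) % 2, steps)
    x = rng.standard_normal((n_subjects * steps, 3))
    return FeatureMatrix(x, ["a", "b", "c"], subs, labels, subs)


class TestLosoFolds:
    def test_one_fold_per_subject(self):
        folds = g.loso_folds(_metadata_fm(58))
        assert len(folds) == 58

    def test_partition_property(self):
        fm = _metadata_fm(12)
        folds = g.loso_folds(fm)
        seen = np.concatenate([te for _, te in folds])
        assert sorted(seen) == list(range(fm.n_steps))
        for tr, te in folds:
            assert set(fm.subject_ids[tr]).isdisjoint(fm.subject_ids[te])
            assert len(set(fm.subject_ids[te])) == 1

    def test_two_subjects(self):
        folds = g.loso_folds(_metadata_fm(2))
        assert len(folds) == 2

    def test_single_subject_rejected(self):
        fm = _metadata_fm(2)
        with pytest.raises(ValueError):
            g.loso_folds(fm.rows(fm.subject_ids == "S000"))

    def test_fold_construction_is_metadata_only(self):
        """Same metadata, different feature values: identical folds."""
        a, b = _metadata_fm(6, seed=1), _metadata_fm(6, seed=2)
        for (tr1, te1), (tr2, te2) in zip(g.loso_folds(a), g.loso_folds(b)):
            np.testing.assert_array_equal(tr1, tr2)
            np.testing.assert_array_equal(te1, te2)


def _preds(votes_per_subject, clf="knn"):
    """votes_per_subject: list of (subject, true, n_pd_steps, n_steps)."""
    rows = []
    for sid, true, n_pd, n in votes_per_subject:
        for i in range(n):
            rows.append(dict(subject_id=sid, y_true=true,
                             y_pred=1 if i < n_pd else 0,
                             classifier=clf, fold=0))
    return pd.DataFrame(rows)


class TestMajorityVote:
    def test_majority_pd(self):
        calls = majority_vote(_preds([("A", 1, 12, 20)]))
        assert calls.iloc[0]["y_pred"] == 1

    def test_exact_tie_defaults_to_pd(self):
        calls = majority_vote(_preds([("A", 0, 10, 20)]))
        assert calls.iloc[0]["y_pred"] == 1
        calls = majority_vote(_preds([("A", 0, 10, 20)]), tie="control")
        assert calls.iloc[0]["y_pred"] == 0

    def test_no_pd_steps_gives_control(self):
        calls = majority_vote(_preds([("A", 0, 0, 19)]))
        assert calls.iloc[0]["y_pred"] == 0

    def test_unknown_subject_rejected(self):
        with pytest.raises(ValueError):
            majority_vote(_preds([("A", 1, 3, 5)]), subject_id="Z")


class TestSummarize:
    def test_table5_confusion_counts(self):
        """TP=23 TN=26 FP=6 FN=3 -> accuracy 84.5%, sens 88.5%, spec 81.3%."""
        subjects = ([(f"P{i}", 1, 8, 10) for i in range(23)] +     # true PD, called PD
                    [(f"Q{i}", 1, 2, 10) for i in range(3)] +      # true PD, missed
                    [(f"C{i}", 0, 1, 10) for i in range(26)] +     # control, correct
                    [(f"D{i}", 0, 9, 10) for i in range(6)])       # control, false pos
        ev = g.summarize(_preds(subjects))
        assert ev.tp == 23 and ev.tn == 26 and ev.fp == 6 and ev.fn == 3
        assert ev.n_subjects == 58
        assert 100 * ev.subject_accuracy == pytest.approx(84.5, abs=0.05)
        assert 100 * ev.subject_sensitivity == pytest.approx(88.5, abs=0.05)
        assert 100 * ev.subject_specificity == pytest.approx(81.3, abs=0.05)
        assert ev.misclassification_rate == pytest.approx(1 - ev.subject_accuracy)

    def test_all_correct(self):
        ev = g.summarize(_preds([("A", 1, 10, 10), ("B", 0, 0, 10)]))
        assert ev.step_accuracy == ev.subject_accuracy == 1.0
        assert ev.step_sensitivity == ev.step_specificity == 1.0
        assert ev.misclassification_rate == 0.0

    def test_coin_flip_predictions_near_half(self):
        rng = np.random.default_rng(0)
        n = 4000
        df = pd.DataFrame(dict(
            subject_id=np.repeat([f"S{i}" for i in range(200)], 20),
            y_true=np.repeat(np.arange(200) % 2, 20),
            y_pred=rng.integers(0, 2, n), classifier="knn", fold=0))
        ev = g.summarize(df)
        half_width = 1.96 * 0.5 / np.sqrt(n)
        assert abs(ev.step_accuracy - 0.5) < 3 * half_width


class TestCochranQ:
    def test_identical_columns(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 2, 30)
        q, p = g.cochran_q(np.column_stack([col, col]))
        assert q == 0.0 and p == 1.0

    def test_k2_equals_mcnemar_statistic(self):
        """For two classifiers Q reduces to the uncorrected McNemar chi2."""
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.integers(0, 2, size=(40, 2))
            q, _ = g.cochran_q(x)
            b = np.sum((x[:, 0] == 1) & (x[:, 1] == 0))
            c = np.sum((x[:, 0] == 0) & (x[:, 1] == 1))
            expected = 0.0 if b + c == 0 else (b - c) ** 2 / (b + c)
            assert q == pytest.approx(expected, rel=1e-12)

    def test_small_matrix_matches_formula_and_statsmodels(self):
        x = np.array([[1, 1, 0], [1, 0, 0], [1, 1, 1],
                      [0, 1, 0], [1, 1, 0], [0, 0, 1]])
        q, p = g.cochran_q(x)
        # direct formula evaluation
        k, col, row = 3, x.sum(0), x.sum(1)
        q_direct = k * (k - 1) * ((col - col.mean()) ** 2).sum() / \
            (k * row.sum() - (row ** 2).sum())
        assert q == pytest.approx(q_direct, rel=1e-12)
        res = sm_cochrans_q(x)
        assert q == pytest.approx(res.statistic, rel=1e-10)
        assert p == pytest.approx(res.pvalue, rel=1e-10)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            g.cochran_q(np.array([[1, 2], [0, 1]]))
        with pytest.raises(ValueError):
            g.cochran_q(np.ones((1, 3)))


class TestPosthoc:
    def test_identical_pair_flagged_similar(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, 60)
        b = rng.integers(0, 2, 60)
        x = np.column_stack([a, a, b])
        res = g.posthoc_pairwise(x)
        assert res.pairwise.iloc[0, 1] >= 0.01
        assert ("0", "1") in res.similar_pairs()

    @pytest.mark.parametrize("method", ["dunn", "mcnemar"])
    def test_strongly_discordant_pair_significant(self, method):
        x = np.column_stack([np.ones(120, int), np.zeros(120, int)])
        res = g.posthoc_pairwise(x, method=method)
        assert res.pairwise.iloc[0, 1] < 0.01

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 2, size=(50, 4))
        res = g.posthoc_pairwise(x)
        pm = res.pairwise.to_numpy()
        np.testing.assert_allclose(pm, pm.T)
        np.testing.assert_allclose(np.diag(pm), 1.0)
        assert ((pm >= 0) & (pm <= 1)).all()

    def test_mcnemar_backend_vs_statsmodels(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 2, 40)
        b = rng.integers(0, 2, 40)
        res = g.posthoc_pairwise(np.column_stack([a, b]), method="mcnemar")
        table = [[np.sum((a == 1) & (b == 1)), np.sum((a == 1) & (b == 0))],
                 [np.sum((a == 0) & (b == 1)), np.sum((a == 0) & (b == 0))]]
        exact = (table[0][1] + table[1][0]) < 25
        expected = float(sm_mcnemar(table, exact=exact, correction=True).pvalue)
        assert res.pairwise.iloc[0, 1] == pytest.approx(min(expected, 1.0))


class TestCorrectnessMatrix:
    def test_step_level_shape(self, separable_fm):
        preds = g.run_loso(separable_fm, [g.ClassifierSpec("lda"),
                                          g.ClassifierSpec("naive_bayes")])
        m = correctness_matrix(preds, level="step")
        assert m.shape == (separable_fm.n_steps, 2)
        assert set(np.unique(m)) <= {0, 1}

    def test_subject_level_shape(self, separable_fm):
        preds = g.run_loso(separable_fm, [g.ClassifierSpec("lda"),
                                          g.ClassifierSpec("naive_bayes")])
        m = correctness_matrix(preds, level="subject")
        assert m.shape == (8, 2)
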