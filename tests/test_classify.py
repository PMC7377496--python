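"""Classifier-bank behaviour: specs, leakage-free scaling, RF repetition."""

import numpy as np
import pytest

import gaitpd as g
from gaitpd.classify import (CLASSIFIER_NAMES, DETERMINISTIC_CLASSIFIERS,
                             ClassifierSpec, default_bank, fit_predict,
                             rf_repeated)
from gaitpd.features import FeatureMatrix

from conftest import make_separable_fm


def _split(fm, holdout="S00"):
    test_mask = fm.subject_ids == holdout
    return fm.rows(~test_mask), fm.rows(test_mask)


class TestSpecs:
    def test_bank_has_nine_members(self):
        bank = default_bank()
        assert [s.name for s in bank] == list(CLASSIFIER_NAMES)

    def test_default_knn_k_is_49_and_odd(self):
        bank = {s.name: s for s in default_bank()}
        assert bank["knn"].params["k"] == 49
        assert bank["knn"].params["k"] % 2 == 1
        assert bank["random_forest"].params["n_repeats"] == 11

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("knn", params={"k": 48})

    def test_even_repeats_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("random_forest", params={"n_repeats": 10})

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("neural_net")


class TestFitPredict:
    @pytest.mark.parametrize("name", CLASSIFIER_NAMES)
    def test_separable_data_classified_perfectly_loso(self, name):
        fm = make_separable_fm(n_subjects=8, steps_per_subject=10)
        params = {"k": 9} if name == "knn" else {}
        spec = ClassifierSpec(name, params=params, seed=1)
        preds = g.run_loso(fm, [spec])
        assert (preds["y_true"] == preds["y_pred"]).all()
        assert set(preds["y_pred"]) <= {0, 1}

    def test_single_class_training_rejected(self, separable_fm):
        train, test = _split(separable_fm)
        bad = train.rows(train.labels == 1)
        with pytest.raises(ValueError):
            fit_predict(ClassifierSpec("lda"), bad, test)

    def test_nonfinite_features_rejected_at_construction(self):
        x = np.ones((4, 2))
        x[0, 0] = np.inf
        with pytest.raises(ValueError):
            FeatureMatrix(x, ["a", "b"], np.array(["s"] * 4),
                          np.array([0, 1, 0, 1]), np.array(["r"] * 4))

    def test_knn_k_exceeding_train_rejected(self, separable_fm):
        train, test = _split(separable_fm)
        with pytest.raises(ValueError):
            fit_predict(ClassifierSpec("knn", params={"k": 9999}), train, test)

    def test_memorization_bound(self, separable_fm):
        train, test = _split(separable_fm)
        spec = ClassifierSpec("tree")
        on_train = fit_predict(spec, train, train)
        held_out = fit_predict(spec, train, test)
        assert (on_train["y_true"] == on_train["y_pred"]).mean() >= \
               (held_out["y_true"] == held_out["y_pred"]).mean()

    @pytest.mark.parametrize("name", DETERMINISTIC_CLASSIFIERS)
    def test_training_row_permutation_invariance(self, name):
        fm = make_separable_fm(n_subjects=6, gap=1.0, seed=5)
        train, test = _split(fm)
        params = {"k": 7} if name == "knn" else {}
        spec = ClassifierSpec(name, params=params)
        base = fit_predict(spec, train, test)["y_pred"]
        rng = np.random.default_rng(0)
        perm = rng.permutation(train.n_steps)
        shuffled = FeatureMatrix(train.values[perm], train.feature_names,
                                 train.subject_ids[perm], train.labels[perm],
                                 train.recording_ids[perm])
        np.testing.assert_array_equal(
            fit_predict(spec, shuffled, test)["y_pred"], base)

    def test_scaler_fit_on_train_only(self, separable_fm):
        """Replacing test rows by wild sentinels must not change the fit."""
        train, test = _split(separable_fm)
        spec = ClassifierSpec("logreg")
        base = fit_predict(spec, train, test)["y_pred"]
        sentinel = FeatureMatrix(test.values * 1e6, test.feature_names,
                                 test.subject_ids, test.labels,
                                 test.recording_ids)
        est = g.classify.build_estimator(spec)
        est.fit(train.values, train.labels)
        # scaler statistics identical whether or not the sentinel test exists
        np.testing.assert_array_equal(est.named_steps["scale"].mean_,
                                      g.classify.build_estimator(spec).fit(
                                          train.values, train.labels
                                      ).named_steps["scale"].mean_)
        assert len(base) == test.n_steps


class TestRfRepeated:
    def test_single_repeat_equals_fit_predict(self, separable_fm):
        train, test = _split(separable_fm)
        spec = ClassifierSpec("random_forest", seed=3)
        one = rf_repeated(spec, train, test, n_repeats=1)
        # the single repeat uses the first derived seed, not spec.seed
        seed0 = int(np.random.SeedSequence(3).generate_state(1)[0] % 2**31)
        direct = fit_predict(ClassifierSpec("random_forest", seed=seed0),
                             train, test)
        np.testing.assert_array_equal(one["y_pred"], direct["y_pred"])

    def test_even_repeats_rejected(self, separable_fm):
        train, test = _split(separable_fm)
        with pytest.raises(ValueError):
            rf_repeated(ClassifierSpec("random_forest"), train, test, n_repeats=4)

    def test_fixed_seed_bit_identical(self, separable_fm):
        train, test = _split(separable_fm)
        spec = ClassifierSpec("random_forest", seed=11)
        a = rf_repeated(spec, train, test, n_repeats=5)
        b = rf_repeated(spec, train, test, n_repeats=5)
        np.testing.assert_array_equal(a["y_pred"], b["y_pred"])
        np.testing.assert_array_equal(a["pd_votes"], b["pd_votes"])

    def test_odd_votes_never_tie(self, separable_fm):
        train, test = _split(separable_fm)
        out = rf_repeated(ClassifierSpec("random_forest", seed=2),
                          train, test, n_repeats=5)
        assert not np.any(out["pd_votes"] * 2 == out["n_repeats"])
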