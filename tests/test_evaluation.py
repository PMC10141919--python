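"""Classifiers, cross-validation schemes, metrics, ROC, transfer,
permutation importance."""

import numpy as np
import pandas as pd
import pytest

from flowsense import evaluation as ev


class TestMetricsFromConfusion:
    @pytest.mark.parametrize(
        "cm, precision, recall, f1",
        [
            # the five-participant study's pooled logistic matrix
            (ev.ConfusionMatrix(tn=26, fp=12, fn=5, tp=17), 0.75, 0.72, 0.72),
            # its naive Bayes matrix
            (ev.ConfusionMatrix(tn=24, fp=14, fn=8, tp=14), 0.66, 0.63, 0.64),
            # the daily-use study's naive Bayes matrix
            (ev.ConfusionMatrix(tn=3, fp=1, fn=1, tp=5), 0.80, 0.80, 0.80),
        ],
    )
    def test_weighted_metrics_reproduce_reference_values(self, cm, precision,
                                                        recall, f1):
        p, r, f = ev.metrics_from_confusion(cm)
        assert p == pytest.approx(precision, abs=5e-3)
        assert r == pytest.approx(recall, abs=5e-3)
        assert f == pytest.approx(f1, abs=5e-3)

    def test_perfect_predictions(self):
        p, r, f = ev.metrics_from_confusion(ev.ConfusionMatrix(10, 0, 0, 10))
        assert (p, r, f) == (1.0, 1.0, 1.0)

    def test_weighted_recall_equals_accuracy(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tn, fp, fn, tp = rng.integers(0, 30, size=4)
            if tn + fp == 0 or fn + tp == 0:
                continue
            cm = ev.ConfusionMatrix(int(tn), int(fp), int(fn), int(tp))
            _, recall, _ = ev.metrics_from_confusion(cm)
            assert recall == pytest.approx((tn + tp) / cm.total)

    def test_division_by_zero_cell_warns_and_zeroes(self):
        cm = ev.ConfusionMatrix(tn=10, fp=0, fn=5, tp=0)  # nothing predicted flow
        with pytest.warns(UserWarning, match="division by zero"):
            p, r, f = ev.metrics_from_confusion(cm)
        assert 0 <= f < 1

    def test_empty_matrix_errors(self):
        with pytest.raises(ev.EvaluationError):
            ev.metrics_from_confusion(ev.ConfusionMatrix(0, 0, 0, 0))

    def test_agrees_with_sklearn_weighted_average(self):
        from sklearn.metrics import precision_recall_fscore_support
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 100)
        pred = rng.integers(0, 2, 100)
        cm = ev.ConfusionMatrix.from_predictions(y, pred)
        ours = ev.metrics_from_confusion(cm)
        theirs = precision_recall_fscore_support(y, pred, average="weighted",
                                                 zero_division=0)[:3]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)


class TestROC:
    def test_probabilities_equal_labels(self):
        assert ev.roc_auc([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert ev.roc_auc([0.4] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_matches_brute_force_pair_count(self):
        rng = np.random.default_rng(2)
        p = np.round(rng.random(50), 2)  # duplicates force tie handling
        y = rng.integers(0, 2, 50)
        pos = p[y == 1]
        neg = p[y == 0]
        pairs = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg)
        assert ev.roc_auc(p, y) == pytest.approx(pairs / (len(pos) * len(neg)))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        p = rng.random(40)
        y = rng.integers(0, 2, 40)
        assert ev.roc_auc(p, y) == pytest.approx(ev.roc_auc(np.exp(3 * p), y))

    def test_single_class_errors(self):
        with pytest.raises(ev.EvaluationError, match="one class"):
            ev.roc_auc([0.1, 0.9], [1, 1])

    def test_roc_table_enumerates_thresholds(self):
        p = np.array([0.1, 0.4, 0.4, 0.8])
        y = np.array([0, 0, 1, 1])
        table = ev.roc_table(p, y)
        assert len(table) == 4  # three distinct probabilities + top corner
        top = table.iloc[-1]
        assert top.tpr == 0 and top.tnr == 1
        bottom = table.iloc[0]
        assert bottom.tpr == 1 and bottom.tnr == 0


class TestClassifiers:
    def test_nb_midpoint_symmetry(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        clf = ev.train_classifier("gaussian_nb", X, y)
        assert clf.predict_proba([[0.0]])[0, 1] == pytest.approx(0.5)

    def test_nb_posterior_matches_hand_computed_bayes_rule(self):
        X = np.array([[0.0], [2.0], [4.0], [6.0]])
        y = np.array([0, 0, 1, 1])
        clf = ev.train_classifier("gaussian_nb", X, y)
        # class 0: mean 1, var 1; class 1: mean 5, var 1; equal priors
        x = 2.5
        from scipy.stats import norm
        like0 = norm.pdf(x, 1, 1)
        like1 = norm.pdf(x, 5, 1)
        expected = like1 / (like0 + like1)
        assert clf.predict_proba([[x]])[0, 1] == pytest.approx(expected, rel=1e-6)

    def test_single_class_training_errors(self):
        with pytest.raises(ev.EvaluationError, match="single class"):
            ev.train_classifier("logistic", np.ones((4, 1)), [1, 1, 1, 1])

    def test_unknown_kind_errors(self):
        with pytest.raises(ev.EvaluationError, match="unknown"):
            ev.train_classifier("svm", np.ones((4, 1)), [0, 1, 0, 1])

    def test_resubstitution_beats_between_participant_on_average(
            self, study1_table):
        from flowsense import features as ft
        feats = list(ft.FEATURE_NAMES[:8])
        resub, between = [], []
        for seed in range(5):
            resub.append(ev.cross_validate(
                study1_table, "resubstitution", "logistic", feats,
                seed=seed).metrics.auc)
            between.append(ev.cross_validate(
                study1_table, "between_participant", "logistic", feats,
                seed=seed).metrics.auc)
        assert np.mean(resub) >= np.mean(between)


class TestCrossValidation:
    def test_between_participant_has_one_fold_per_participant(self, study1_table):
        res = ev.cross_validate(study1_table, "between_participant",
                                "logistic", ["median_diff_TEMP"], seed=0)
        assert res.confusion.total == 60
        assert len(res.probabilities) == 60

    def test_between_participant_never_leaks_participants(self, study1_table):
        table = study1_table.reset_index(drop=True)
        folds = list(ev._fold_indices(table, "between_participant", 0,
                                      "flow", "participant_id"))
        assert len(folds) == table["participant_id"].nunique()
        for train, test in folds:
            assert not (set(table.participant_id.iloc[train])
                        & set(table.participant_id.iloc[test]))

    @pytest.mark.parametrize("scheme", ["between_participant",
                                        "stratified_10fold", "leave_one_out"])
    def test_test_sets_partition_rows(self, study1_table, scheme):
        table = study1_table.reset_index(drop=True)
        folds = list(ev._fold_indices(table, scheme, 3, "flow", "participant_id"))
        seen = np.concatenate([test for _, test in folds])
        assert sorted(seen) == list(range(len(table)))

    def test_stratified_folds_balance_labels(self, study1_table):
        table = study1_table.reset_index(drop=True)
        folds = list(ev._fold_indices(table, "stratified_10fold", 0,
                                      "flow", "participant_id"))
        assert len(folds) == 10
        per_fold_flow = [table["flow"].iloc[test].sum() for _, test in folds]
        assert max(per_fold_flow) - min(per_fold_flow) <= 2

    def test_resubstitution_with_memorizing_classifier_is_perfect(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame({
            "participant_id": ["P1", "P2"] * 10,
            "x": np.arange(20, dtype=float),  # unique values: memorizable
            "flow": rng.integers(0, 2, 20),
        })
        # a 1-NN-style memorizer: logistic on a feature equal to the label
        table["x"] = table["flow"].astype(float)
        res = ev.cross_validate(table, "resubstitution", "logistic", ["x"])
        assert res.metrics.f1 == 1.0

    def test_single_class_training_fold_skipped_with_warning(self):
        table = pd.DataFrame({
            "participant_id": ["P1"] * 4 + ["P2"] * 4,
            "x": np.r_[np.zeros(4), np.ones(4)],
            "flow": [0, 0, 0, 0, 1, 1, 1, 1],
        })
        with pytest.warns(UserWarning, match="one class"):
            with pytest.raises(ev.EvaluationError):
                # both training folds are single-class here
                ev.cross_validate(table, "between_participant", "logistic",
                                  ["x"])

    def test_deterministic_given_seed(self, study1_table):
        a = ev.cross_validate(study1_table, "stratified_10fold", "logistic",
                              ["skewness_TEMP", "kurtosis_ACC_Y"], seed=7)
        b = ev.cross_validate(study1_table, "stratified_10fold", "logistic",
                              ["skewness_TEMP", "kurtosis_ACC_Y"], seed=7)
        pd.testing.assert_series_equal(a.probabilities, b.probabilities)


class TestTransfer:
    def _model(self, coefs, intercept=0.0):
        return ev.FrozenLogisticModel(
            intercept=intercept, coefficients=pd.Series(coefs))

    def test_zero_coefficients_give_half_auc(self, study1_table):
        model = self._model({"median_diff_TEMP": 0.0}, intercept=0.3)
        metrics, probs = ev.transfer_predict(model, study1_table)
        assert metrics.auc == 0.5
        assert probs.nunique() == 1

    def test_transfer_to_training_table_matches_resubstitution(self, study1_table):
        feats = ["median_diff_TEMP", "kurtosis_ACC_Y"]
        clf = ev.train_classifier("logistic", study1_table[feats],
                                  study1_table["flow"])
        model = ev.FrozenLogisticModel(
            intercept=float(clf.intercept_[0]),
            coefficients=pd.Series(clf.coef_[0], index=feats))
        metrics, _ = ev.transfer_predict(model, study1_table)
        resub = ev.cross_validate(study1_table, "resubstitution", "logistic",
                                  feats)
        assert metrics.auc == pytest.approx(resub.metrics.auc, abs=1e-9)
        assert metrics.f1 == pytest.approx(resub.metrics.f1, abs=1e-9)

    def test_permuted_features_destroy_transfer(self, study1_table):
        rng = np.random.default_rng(5)
        feats = ["median_diff_TEMP", "skewness_TEMP", "kurtosis_ACC_Y"]
        clf = ev.train_classifier("logistic", study1_table[feats],
                                  study1_table["flow"])
        model = ev.FrozenLogisticModel(
            intercept=float(clf.intercept_[0]),
            coefficients=pd.Series(clf.coef_[0], index=feats))
        aucs = []
        for _ in range(20):
            shuffled = study1_table.copy()
            for f in feats:
                shuffled[f] = rng.permutation(shuffled[f].to_numpy())
            metrics, _ = ev.transfer_predict(model, shuffled)
            aucs.append(metrics.auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)

    def test_feature_mismatch_is_schema_error(self, study1_table):
        model = self._model({"not_a_feature": 1.0})
        with pytest.raises(ev.EvaluationError, match="lacks"):
            ev.transfer_predict(model, study1_table)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(6)
    n = 400
    X = pd.DataFrame({
        "signal": rng.standard_normal(n),
        "noise": rng.standard_normal(n),
    })
    y = (rng.random(n) < 1 / (1 + np.exp(-3 * X["signal"]))).astype(int)
    clf = ev.train_classifier("logistic", X, y)
    return clf, X, y


class TestPermutationImportance:
    def test_null_feature_has_no_importance(self, fitted):
        clf, X, y = fitted
        imp = ev.permutation_importance(clf, X, y, n_shuffles=100, seed=0)
        row = imp.importance.loc["noise"]
        assert abs(row.mean_auc_drop) < 2 * row.sd_auc_drop / np.sqrt(100) + 0.01

    def test_sole_informative_feature_drops_to_chance(self, fitted):
        clf, X, y = fitted
        imp = ev.permutation_importance(clf, X, y, n_shuffles=100, seed=0)
        expected = imp.baseline_auc - 0.5
        assert imp.importance.loc["signal", "mean_auc_drop"] == pytest.approx(
            expected, abs=0.05)

    def test_identical_seed_identical_result(self, fitted):
        clf, X, y = fitted
        a = ev.permutation_importance(clf, X, y, n_shuffles=20, seed=9)
        b = ev.permutation_importance(clf, X, y, n_shuffles=20, seed=9)
        pd.testing.assert_frame_equal(a.importance, b.importance)

    def test_shuffle_count_validated(self, fitted):
        clf, X, y = fitted
        with pytest.raises(ev.EvaluationError):
            ev.permutation_importance(clf, X, y, n_shuffles=0, seed=0)
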