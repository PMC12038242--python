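"""Feature selection, SVM classification, ROC/AUC, cross-validation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from circkit import classify as cls
from circkit.synth import simulate_cohort_matrix


def _cohort_xy(n_features, n_per_class, n_informative, seed, effect=2.0, dispersion=0.1):
    cm = simulate_cohort_matrix(
        n_features, n_per_class, n_informative, effect_log2fc=effect,
        dispersion=dispersion, seed=seed,
    )
    X = np.log2(cm.counts + 1.0)
    y = (cm.design["class"] == "disease").astype(int).to_numpy()
    return cm, X, y


class TestSelectDeFeatures:
    def test_both_cuts_required(self):
        res = pd.DataFrame(
            {"log2FoldChange": [2.0, 0.5, 2.0], "padj": [0.001, 0.001, 0.5]},
            index=["in", "small_fc", "weak_p"],
        )
        assert cls.select_de_features(res) == ["in"]

    def test_empty_selection_warns(self):
        res = pd.DataFrame({"log2FoldChange": [0.1], "padj": [0.9]}, index=["x"])
        with pytest.warns(UserWarning):
            assert cls.select_de_features(res) == []


class TestInformationGain:
    def test_perfect_separator_one_bit(self):
        assert cls.information_gain([1.0, 1.1, 9.0, 9.1], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_constant_feature_zero(self):
        assert cls.information_gain([3.0, 3.0, 3.0, 3.0], [0, 0, 1, 1]) == 0.0

    def test_exhaustive_threshold_example(self):
        # threshold between 2 and 3 splits labels perfectly -> 1 bit
        assert cls.information_gain([1, 2, 3, 4], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        """Oracle: enumerate every threshold and compute entropies directly."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.integers(0, 2, size=12)

            def h(lab):
                if len(lab) == 0:
                    return 0.0
                p = np.bincount(lab, minlength=2) / len(lab)
                p = p[p > 0]
                return float(-(p * np.log2(p)).sum())

            best = min(
                (len(y[x <= t]) / 12) * h(y[x <= t]) + (len(y[x > t]) / 12) * h(y[x > t])
                for t in np.unique(x)[:-1]
            )
            assert cls.information_gain(x, y) == pytest.approx(h(y) - best, abs=1e-12)


class TestForestImportance:
    def test_separating_feature_ranks_top(self):
        cm, X, y = _cohort_xy(51, 15, 1, seed=6, effect=4.0, dispersion=0.05)
        imp = cls.forest_importance(X, y, n_trees=300, seed=1)
        assert imp.idxmax() == cm.truth["informative"][0]

    def test_deterministic_given_seed(self):
        _cm, X, y = _cohort_xy(30, 10, 3, seed=7)
        a = cls.forest_importance(X, y, n_trees=100, seed=2)
        b = cls.forest_importance(X, y, n_trees=100, seed=2)
        pd.testing.assert_series_equal(a, b)

    def test_single_class_rejected(self):
        _cm, X, _y = _cohort_xy(10, 4, 0, seed=8)
        with pytest.raises(ValueError):
            cls.forest_importance(X, np.zeros(8, dtype=int))


class TestCombineRanks:
    def test_rank_sum_ordering(self):
        ig = pd.Series({"A": 3.0, "B": 2.0, "C": 1.0})   # ig ranks A=1 B=2 C=3
        imp = pd.Series({"A": 0.1, "B": 0.9, "C": 0.5})  # imp ranks B=1 C=2 A=3
        out = cls.combine_ranks(ig, imp)
        # sums: A=4, B=3, C=5 -> order B, A, C
        assert list(out.index) == ["B", "A", "C"]
        assert out["combined_rank"].tolist() == [1, 2, 3]

    def test_tie_broken_by_ig_rank(self):
        ig = pd.Series({"A": 2.0, "B": 1.0})   # ig ranks A=1 B=2
        imp = pd.Series({"A": 0.1, "B": 0.2})  # imp ranks B=1 A=2; sums tie at 3
        out = cls.combine_ranks(ig, imp)
        assert list(out.index) == ["A", "B"]

    def test_identical_rankings_preserved(self):
        ig = pd.Series({"A": 3.0, "B": 2.0, "C": 1.0})
        imp = pd.Series({"A": 0.9, "B": 0.5, "C": 0.1})
        out = cls.combine_ranks(ig, imp)
        assert list(out.index) == ["A", "B", "C"]

    def test_mismatched_features_rejected(self):
        with pytest.raises(ValueError):
            cls.combine_ranks(pd.Series({"A": 1.0}), pd.Series({"B": 1.0}))


class TestAuc:
    def test_worked_example(self):
        # pos {0.9, 0.4}, neg {0.5, 0.1}: concordant pairs 3 of 4
        assert cls.auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_degenerate_cases(self):
        assert cls.auc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0
        assert cls.auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cls.auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_and_sklearn(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            y = np.zeros(n, dtype=int)
            y[: int(rng.integers(1, n))] = 1
            rng.shuffle(y)
            s = np.round(rng.random(n), 2)
            ours = cls.auc(s, y)
            brute = np.mean(
                [
                    1.0 if sp > sn else 0.5 if sp == sn else 0.0
                    for sp in s[y == 1]
                    for sn in s[y == 0]
                ]
            )
            assert ours == pytest.approx(brute, abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestSvm:
    def test_separable_training_auc_one(self):
        X = pd.DataFrame(
            {"s%d" % i: [v, -v] for i, v in enumerate([-3, -2.5, -2, 2, 2.5, 3])},
            index=["f1", "f2"],
        )
        y = np.array([0, 0, 0, 1, 1, 1])
        model = cls.tune_and_train_svm(X, y, inner_cv_folds=3, seed=1)
        roc = cls.evaluate_on_cohort(model, X, y)
        assert roc.auc == 1.0

    def test_deterministic_hyperparameter_choice(self):
        _cm, X, y = _cohort_xy(20, 12, 5, seed=10)
        m1 = cls.tune_and_train_svm(X, y, seed=3)
        m2 = cls.tune_and_train_svm(X, y, seed=3)
        assert m1.best_params_ == m2.best_params_

    def test_missing_test_feature_rejected(self):
        _cm, X, y = _cohort_xy(10, 6, 2, seed=11)
        model = cls.tune_and_train_svm(X, y, seed=1)
        with pytest.raises(KeyError):
            cls.evaluate_on_cohort(model, X.iloc[1:], y)

    def test_single_test_sample_per_class_degenerate_roc(self):
        _cm, X, y = _cohort_xy(10, 10, 3, seed=12, effect=3.0)
        model = cls.tune_and_train_svm(X, y, seed=1)
        sub = [0, len(y) - 1]  # one sample of each class
        roc = cls.evaluate_on_cohort(model, X.iloc[:, sub], y[sub])
        assert roc.auc in (0.0, 0.5, 1.0)


class TestKfoldCv:
    def test_every_sample_scored_once(self):
        _cm, X, y = _cohort_xy(15, 12, 3, seed=13)
        roc = cls.kfold_cv_classify(X, y, k=4, seed=1)
        assert roc.scores.shape == (24,)
        assert np.isfinite(roc.scores).all()

    def test_separable_data_pooled_auc_one(self):
        _cm, X, y = _cohort_xy(20, 10, 8, seed=14, effect=5.0, dispersion=0.02)
        roc = cls.kfold_cv_classify(X, y, k=2, seed=1)
        assert roc.auc == 1.0

    def test_k_exceeding_n_rejected(self):
        _cm, X, y = _cohort_xy(5, 3, 0, seed=15)
        with pytest.raises(ValueError):
            cls.kfold_cv_classify(X, y, k=10)

    def test_fold_internal_selection_does_not_leak(self):
        """On pure noise, selecting features on the pooled data before CV
        inflates the pooled AUC (classic selection leakage); running the
        same selection inside each training fold stays at chance."""
        rng = np.random.default_rng(16)
        n = 40
        y = np.array([0, 1] * (n // 2))
        X = pd.DataFrame(
            rng.normal(size=(400, n)), index=[f"f{i}" for i in range(400)],
            columns=[f"s{i}" for i in range(n)],
        )
        # leaky: pick the 5 best-separating noise features using ALL samples
        ranks_pooled = cls.rank_features(X, y, n_trees=100, seed=2)
        leaky_top = list(ranks_pooled.index[:5])
        leaky = cls.kfold_cv_classify(
            X.loc[leaky_top], y, k=5,
            learner=lambda m, yy, s: cls.tune_and_train_svm(m, yy, seed=s), seed=2,
        )
        # proper: the identical selection refit inside every training fold
        proper = cls.kfold_cv_classify(
            X, y, k=5, learner=cls.DualRankSvmLearner(n_features=5, n_trees=100), seed=2
        )
        assert leaky.auc > 0.65  # the bias the fold-internal path must avoid
        assert 0.3 <= proper.auc <= 0.7

    def test_roc_curve_monotone(self):
        _cm, X, y = _cohort_xy(15, 10, 5, seed=17)
        roc = cls.kfold_cv_classify(X, y, k=4, seed=3)
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()
        assert 0.0 <= roc.auc <= 1.0
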