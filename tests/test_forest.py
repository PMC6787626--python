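import numpy as np
import pandas as pd
import pytest

from tests.conftest import SEP_FEATURES, separable_config
from wstkit.forest import (
    RFParams,
    TreeParams,
    cohen_kappa,
    compare_ensembles,
    correctly_predicted_subset,
    fit_decision_tree,
    fit_rf,
)
from wstkit.scoring import score_table
from wstkit.synthetic import generate_cohort


class TestFitRf:
    def test_separable_cohort_high_oob_accuracy(self, separable_model):
        assert 1 - separable_model.oob_error_overall > 0.90

    def test_shifted_marker_top_ranked_on_both_importances(self, separable_model):
        assert separable_model.ranking("permutation")[0] == "marker_sep"
        assert separable_model.ranking("gini")[0] == "marker_sep"

    def test_confusion_identities(self, separable_model):
        m = separable_model
        conf = m.oob_confusion
        # row sums are the class sizes
        _, counts = np.unique(m.labels, return_counts=True)
        assert np.array_equal(conf.sum(axis=1), counts)
        # diagonal / total complements the overall error exactly
        assert conf.trace() / conf.sum() == pytest.approx(1 - m.oob_error_overall)
        # per-class errors consistent with rows
        for i in range(conf.shape[0]):
            assert m.oob_error_per_class[i] == pytest.approx(
                1 - conf[i, i] / conf[i].sum()
            )

    def test_vote_fractions_sum_to_one(self, separable_model):
        assert np.allclose(separable_model.oob_votes.sum(axis=1), 1.0)

    def test_deterministic_under_seed(self, separable_cohort):
        X = separable_cohort[SEP_FEATURES]
        y = separable_cohort["class3"].to_numpy()
        a = fit_rf(X, y, RFParams(ntree=50, seed=9))
        b = fit_rf(X, y, RFParams(ntree=50, seed=9))
        assert np.array_equal(a.oob_votes, b.oob_votes)
        assert a.oob_error_overall == b.oob_error_overall

    def test_permuted_labels_chance_level(self, separable_cohort):
        rng = np.random.default_rng(1)
        y = rng.permutation(separable_cohort["class3"].to_numpy())
        m = fit_rf(separable_cohort[SEP_FEATURES], y, RFParams(ntree=300, seed=2))
        majority = 1 / 3  # balanced classes
        assert abs((1 - m.oob_error_overall) - majority) < 0.18

    def test_oob_stability_across_seeds(self, separable_cohort):
        # large forests pin the OOB error down; spread stays under 2 points
        X = separable_cohort[SEP_FEATURES]
        y = separable_cohort["class3"].to_numpy()
        errs = [
            fit_rf(X, y, RFParams(ntree=1500, seed=s,
                                  permutation_importance=False)).oob_error_overall
            for s in (0, 1, 2)
        ]
        assert max(errs) - min(errs) < 0.02

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(ValueError, match="2 classes"):
            fit_rf(X, np.zeros(10, dtype=int))

    def test_tiny_class_rejected(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        y = np.array([0] * 9 + [1])
        with pytest.raises(ValueError, match="imbalance"):
            fit_rf(X, y)

    def test_missing_values_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 3.0, 4.0]})
        with pytest.raises(ValueError, match="missing"):
            fit_rf(X, np.array([0, 0, 1, 1]))


class TestCorrectlyPredictedSubset:
    def test_separable_subset_nearly_full(self, separable_model, separable_cohort):
        sub = correctly_predicted_subset(separable_model, separable_cohort)
        assert len(sub) >= 0.9 * len(separable_cohort)

    def test_permuted_labels_subset_near_chance(self, separable_cohort):
        rng = np.random.default_rng(3)
        y = rng.permutation(separable_cohort["class3"].to_numpy())
        m = fit_rf(separable_cohort[SEP_FEATURES], y, RFParams(ntree=300, seed=4))
        sub = correctly_predicted_subset(m, separable_cohort)
        n, k = len(separable_cohort), 3
        assert abs(len(sub) - n / k) < 0.2 * n

    def test_misaligned_table_rejected(self, separable_model, separable_cohort):
        with pytest.raises(ValueError, match="aligned"):
            correctly_predicted_subset(separable_model, separable_cohort.iloc[:5])

    def test_vanished_class_warns(self, separable_cohort):
        # force zero correct predictions for one class via label corruption
        y = separable_cohort["class3"].to_numpy().copy()
        m = fit_rf(separable_cohort[SEP_FEATURES], y, RFParams(ntree=100, seed=5))
        m.labels = m.labels.copy()
        m.labels[m.labels == 2] = -99  # no prediction can ever equal -99
        with pytest.warns(UserWarning, match="class 2"):
            correctly_predicted_subset(m, separable_cohort)


class TestDecisionTree:
    def test_separable_1d_single_split(self):
        X = pd.DataFrame({"x": np.r_[np.linspace(0, 1, 30), np.linspace(3, 4, 30)]})
        y = np.r_[np.zeros(30, dtype=int), np.ones(30, dtype=int)]
        res = fit_decision_tree(X, y, TreeParams(minsplit=20, cp=0.01, seed=0))
        assert res.n_leaves == 2
        thr = res.tree.tree_.threshold[0]
        assert 1.0 < thr < 3.0
        assert all(r.accuracy == 1.0 for r in res.rules)

    def test_huge_cp_single_leaf(self):
        # weak, overlapping signal: its risk reduction is far below cp=0.99
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x": np.r_[rng.normal(0, 1, 40), rng.normal(0.8, 1, 40)]})
        y = np.r_[np.zeros(40, dtype=int), np.ones(40, dtype=int)]
        with pytest.warns(UserWarning, match="single-leaf"):
            res = fit_decision_tree(X, y, TreeParams(cp=0.99))
        assert res.n_leaves == 1

    def test_hierarchical_splits_follow_structure(self):
        # marker "first" separates class 0 from {1,2}; "second" separates 1 from 2
        # class 0 is the largest so the "first" split buys the most impurity
        rng = np.random.default_rng(0)
        sizes = (60, 30, 30)
        first = np.r_[rng.normal(0, 0.3, 60), rng.normal(5, 0.3, 60)]
        second = np.r_[rng.normal(0, 0.3, 90), rng.normal(5, 0.3, 30)]
        X = pd.DataFrame({"first": first, "second": second})
        y = np.repeat([0, 1, 2], sizes)
        res = fit_decision_tree(X, y, TreeParams(minsplit=20, cp=0.01, seed=0))
        assert res.feature_names[res.tree.tree_.feature[0]] == "first"
        used = {res.feature_names[f] for f in res.tree.tree_.feature if f >= 0}
        assert used == {"first", "second"}

    def test_params_validated(self):
        with pytest.raises(ValueError):
            TreeParams(cp=0.0)
        with pytest.raises(ValueError):
            TreeParams(minsplit=1)


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(np.diag([5, 7, 9])) == 1.0

    def test_independent_marginals_zero(self):
        marg_a, marg_b = np.array([30.0, 70.0]), np.array([40.0, 60.0])
        conf = np.outer(marg_a, marg_b) / 100.0
        assert cohen_kappa(conf) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed(self):
        assert cohen_kappa([[20, 5], [10, 15]]) == pytest.approx(0.40)

    def test_degenerate_marginals(self):
        with pytest.raises(ValueError, match="kappa"):
            cohen_kappa([[10, 0], [0, 0]])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa([[0, 0], [0, 0]])


@pytest.fixture(scope="module")
def small_separable():
    cfg = separable_config(seed=8, n_per_class=30, medians=(80.0, 250.0, 700.0))
    t = score_table(generate_cohort(cfg))
    return t[SEP_FEATURES], t["class3"].to_numpy()


class TestCompareEnsembles:

    def test_all_methods_high_accuracy(self, small_separable):
        X, y = small_separable
        out = compare_ensembles(X, y, cv_folds=3, n_repeats=1, seed=0)
        assert set(out) == {"rf", "gradient_boosting", "svm", "tree_boosting"}
        for m, res in out.items():
            assert res["accuracy"].mean() >= 0.9, m
            assert res["kappa"].mean() >= 0.8, m

    def test_permuted_labels_near_chance(self, small_separable):
        X, y = small_separable
        yp = np.random.default_rng(0).permutation(y)
        out = compare_ensembles(X, yp, methods=("rf", "svm"), cv_folds=3,
                                n_repeats=1, seed=0)
        for m, res in out.items():
            assert abs(res["accuracy"].mean() - 1 / 3) < 0.2, m
            assert abs(np.nanmean(res["kappa"])) < 0.25, m

    def test_single_method_block(self, small_separable):
        X, y = small_separable
        out = compare_ensembles(X, y, methods=("rf",), cv_folds=3, n_repeats=1)
        assert list(out) == ["rf"]

    def test_unknown_method_rejected(self, small_separable):
        X, y = small_separable
        with pytest.raises(ValueError, match="unknown"):
            compare_ensembles(X, y, methods=("mystery",))
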