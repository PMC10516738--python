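"""Nested CV machinery: folds, metrics, tuning, sweeps."""


import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hnart import (
    CohortSpec,
    ConfusionMatrix,
    EvalReport,
    HyperGrid,
    auc_rank,
    balanced_accuracy,
    confusion_metrics,
    generate_feature_table,
    nested_cv_run,
    representative_model,
    stratified_folds,
    sweep_feature_counts,
    tune_hyperparameters,
)
from hnart.selection import build_feature_matrix, FeatureMatrix


def _auc_pairs_oracle(scores, y):
    """Exhaustive positive-negative pair counting with half-credit ties."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestStratifiedFolds:
    def test_study_sized_cohort_balanced(self):
        y = np.array([1] * 50 + [0] * 122)
        plan = stratified_folds(y, k=5, seed=0)
        for fold in plan.folds:
            assert np.sum(y[list(fold)]) == 10
            assert len(fold) in (34, 35)
        flat = sorted(i for fold in plan.folds for i in fold)
        assert flat == list(range(172))

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            stratified_folds(np.ones(20, dtype=int), k=5, seed=0)

    def test_same_seed_identical(self):
        y = np.array([0, 1] * 20)
        assert stratified_folds(y, seed=4) == stratified_folds(y, seed=4)


class TestBalancedAccuracy:
    @pytest.mark.parametrize("cm, expected", [
        (ConfusionMatrix(tp=10, fn=0, tn=10, fp=0), 1.0),
        (ConfusionMatrix(tp=5, fn=5, tn=5, fp=5), 0.5),
        (ConfusionMatrix(tp=7, fn=3, tn=9, fp=1), 0.8),
    ])
    def test_formula(self, cm, expected):
        assert balanced_accuracy(cm) == pytest.approx(expected)

    @pytest.mark.parametrize("n_pos, n_neg", [(1, 99), (30, 70), (50, 50)])
    def test_constant_classifier_is_half_at_any_prevalence(self, n_pos, n_neg):
        always_pos = ConfusionMatrix(tp=n_pos, fn=0, tn=0, fp=n_neg)
        always_neg = ConfusionMatrix(tp=0, fn=n_pos, tn=n_neg, fp=0)
        assert balanced_accuracy(always_pos) == 0.5
        assert balanced_accuracy(always_neg) == 0.5

    def test_missing_class_errors(self):
        with pytest.raises(ValueError):
            balanced_accuracy(ConfusionMatrix(tp=0, fn=0, tn=5, fp=5))


class TestConfusionMetrics:
    def test_perfect_and_worked_example(self):
        perfect = confusion_metrics(ConfusionMatrix(tp=4, fn=0, tn=6, fp=0))
        assert perfect == {"accuracy": 1.0, "sensitivity": 1.0, "specificity": 1.0}
        out = confusion_metrics(ConfusionMatrix(tp=7, fn=3, tn=9, fp=1))
        assert (out["accuracy"], out["sensitivity"], out["specificity"]) == \
            pytest.approx((0.8, 0.7, 0.9))

    def test_absent_class_errors(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionMatrix(tp=3, fn=2, tn=0, fp=0))


class TestAUC:
    def test_separating_tied_and_worked_example(self):
        assert auc_rank([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0
        assert auc_rank([5.0] * 6, [0, 0, 0, 1, 1, 1]) == 0.5
        assert auc_rank([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    @given(st.integers(2, 12).flatmap(lambda n: st.tuples(
        st.lists(st.integers(0, 5), min_size=n, max_size=n),
        st.lists(st.integers(0, 1), min_size=n, max_size=n))))
    @settings(deadline=None, max_examples=120)
    def test_equals_pair_counting_oracle(self, scores_y):
        scores, y = scores_y
        if len(set(y)) < 2:
            return
        assert auc_rank(scores, y) == pytest.approx(_auc_pairs_oracle(scores, y))

    def test_symmetry_and_monotone_invariance(self, rng):
        scores = rng.normal(size=30)
        y = (rng.random(30) < 0.4).astype(int)
        y[:2] = [0, 1]
        a = auc_rank(scores, y)
        assert a + auc_rank(scores, 1 - y) == pytest.approx(1.0)
        assert auc_rank(np.exp(scores * 3), y) == pytest.approx(a)


class TestTuning:
    def _separable(self, n=60):
        y = np.array([0, 1] * (n // 2))
        X = np.column_stack([y * 4.0 + np.linspace(0, 0.1, n), np.ones(n)])
        return X, y

    def test_single_point_grid(self):
        X, y = self._separable()
        grid = ({"criterion": "gini", "max_depth": 3, "n_estimators": 10},)
        assert tune_hyperparameters(X, y, grid, "rf", seed=0) == grid[0]

    def test_separable_reaches_perfect_inner_ba(self):
        X, y = self._separable()
        best = tune_hyperparameters(X, y, HyperGrid.reduced().svm, "svm", seed=0)
        assert best["kernel"] in ("linear", "rbf")

    def test_empty_grid_errors(self):
        X, y = self._separable()
        with pytest.raises(ValueError):
            tune_hyperparameters(X, y, (), "rf", seed=0)

    def test_tie_takes_first_in_canonical_order(self):
        X, y = self._separable()
        # two configs identical in effect: tie resolves to the first listed
        grid = ({"C": 1, "kernel": "linear", "gamma": 0.001},
                {"C": 1, "kernel": "linear", "gamma": 0.0001})
        assert tune_hyperparameters(X, y, grid, "svm", seed=0) == grid[0]


class TestNestedCV:
    def test_report_structure_and_mean(self, null_table):
        fm = build_feature_matrix(null_table, "clin")
        rep = nested_cv_run(fm, "chisq", "rf", 3, seed=0,
                            grid=HyperGrid.reduced())
        assert len(rep.fold_metrics) == 5
        assert rep.mean("auc") == pytest.approx(
            np.mean([m["auc"] for m in rep.fold_metrics]))

    def test_strong_signal_high_auc(self):
        table = generate_feature_table(
            CohortSpec(n_patients=200, imc1_sd=0.05, seed=2))
        fm = build_feature_matrix(table, "clin+rad")
        rep = nested_cv_run(fm, "mrmr", "rf", 3, mode="paper", seed=1,
                            grid=HyperGrid.reduced())
        assert rep.mean("auc") > 0.9

    def test_leak_free_not_above_paper_mode(self):
        aucs = {"paper": [], "leak_free": []}
        for seed in range(3):
            table = generate_feature_table(CohortSpec(n_patients=150, seed=60 + seed))
            fm = build_feature_matrix(table, "clin+rad")
            for mode in aucs:
                rep = nested_cv_run(fm, "chisq", "rf", 5, mode=mode, seed=seed,
                                    grid=HyperGrid.reduced())
                aucs[mode].append(rep.mean("auc"))
        assert np.mean(aucs["leak_free"]) <= np.mean(aucs["paper"]) + 0.02

    def test_too_many_features_errors(self, null_table):
        fm = build_feature_matrix(null_table, "dose")
        with pytest.raises(ValueError):
            nested_cv_run(fm, "chisq", "rf", 99, grid=HyperGrid.reduced())


class TestRepresentativeModel:
    def _report(self, k, auc):
        rep = EvalReport(feature_set="clin", selector="chisq", classifier="rf",
                         mode="paper", n_features=k, seed=0)
        rep.fold_metrics = [{"auc": auc, "accuracy": auc, "sensitivity": auc,
                             "specificity": auc}] * 5
        return rep

    def test_argmax_and_tie_rule(self):
        reports = [self._report(k, a) for k, a in
                   zip(range(1, 6), [0.60, 0.66, 0.61, 0.66, 0.58])]
        best = representative_model(reports)
        assert best.n_features == 2  # tie at 0.66 resolved to fewer features

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            representative_model([])


def test_sweep_reuses_ranking_consistently(null_table):
    fm = build_feature_matrix(null_table, "clin")
    reports = sweep_feature_counts(fm, "chisq", "svm", ks=(1, 3), seed=5,
                                   grid=HyperGrid.reduced())
    assert [r.n_features for r in reports] == [1, 3]
    for r in reports:
        for m in r.fold_metrics:
            assert len(m["features"]) == r.n_features
    # the 1-feature set is a prefix of the 3-feature set fold by fold
    for m1, m3 in zip(reports[0].fold_metrics, reports[1].fold_metrics):
        assert m3["features"][:1] == m1["features"]
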