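"""Nested stratified cross-validation with balanced-accuracy tuning.

The outer 5-fold split estimates generalization; within each outer training
pool an inner stratified 5-fold grid search picks the random-forest or SVM
hyperparameters with the highest mean balanced accuracy, the tuned model is
refit on the whole outer-training pool, and AUC / accuracy / sensitivity /
specificity are measured on the held-out fold.  The reported model metrics are
the arithmetic means over the five outer folds.

Two selection modes are provided.  ``leak_free`` ranks features on each outer
training pool only.  ``paper`` ranks once on the full dataset before
cross-validation — the internal-validation shortcut small cohorts often force,
which carries a positive selection bias; it is kept for fidelity and for
measuring that bias.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cohort import FEATURE_SETS, FeatureTable
from .selection import FeatureMatrix, Ranking, build_feature_matrix, rank_features

__all__ = [
    "FoldPlan",
    "HyperGrid",
    "ConfusionMatrix",
    "EvalReport",
    "stratified_folds",
    "balanced_accuracy",
    "confusion_metrics",
    "auc_rank",
    "tune_hyperparameters",
    "nested_cv_run",
    "sweep_feature_counts",
    "representative_model",
    "run_grid",
    "CLASSIFIERS",
]

CLASSIFIERS = ("rf", "svm")
METRICS = ("auc", "accuracy", "sensitivity", "specificity")


@dataclass(frozen=True)
class FoldPlan:
    """Disjoint stratified test folds covering every patient exactly once."""

    folds: tuple[tuple[int, ...], ...]
    seed: int

    def __post_init__(self) -> None:
        flat = [i for fold in self.folds for i in fold]
        if len(flat) != len(set(flat)):
            raise ValueError("folds must be disjoint")


@dataclass(frozen=True)
class HyperGrid:
    """Hyperparameter grids; list order is the canonical tie-break order."""

    rf: tuple[dict, ...]
    svm: tuple[dict, ...]

    def __post_init__(self) -> None:
        if not self.rf or not self.svm:
            raise ValueError("hyperparameter grids must be non-empty")

    def for_classifier(self, classifier: str) -> tuple[dict, ...]:
        if classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {classifier!r}")
        return self.rf if classifier == "rf" else self.svm

    @classmethod
    def default(cls) -> "HyperGrid":
        """The full search space: RF criterion/depth/size, SVM C/kernel/gamma."""
        rf = tuple({"criterion": c, "max_depth": d, "n_estimators": n}
                   for c, d, n in itertools.product(
                       ("gini", "entropy"), range(3, 12),
                       (10, 50, 100, 500, 1000, 2000)))
        svm = tuple({"C": c, "kernel": k, "gamma": g}
                    for c, k, g in itertools.product(
                        (1, 10, 100, 1000),
                        ("linear", "rbf", "poly", "sigmoid"),
                        (0.001, 0.0001)))
        return cls(rf=rf, svm=svm)

    @classmethod
    def reduced(cls) -> "HyperGrid":
        """Coarse grid with the same axes, for desk-scale sweeps."""
        rf = tuple({"criterion": c, "max_depth": d, "n_estimators": 10}
                   for c, d in itertools.product(("gini", "entropy"), (3, 7)))
        svm = tuple({"C": c, "kernel": k, "gamma": 0.001}
                    for c, k in itertools.product((1, 100), ("linear", "rbf")))
        return cls(rf=rf, svm=svm)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with reduction as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray
                         ) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(tp=int(np.sum((y_true == 1) & (y_pred == 1))),
                   fn=int(np.sum((y_true == 1) & (y_pred == 0))),
                   tn=int(np.sum((y_true == 0) & (y_pred == 0))),
                   fp=int(np.sum((y_true == 0) & (y_pred == 1))))


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Mean of sensitivity and specificity: (TP/(TP+FN) + TN/(TN+FP)) / 2."""
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise ValueError("balanced accuracy needs both classes in the set")
    return 0.5 * (cm.tp / (cm.tp + cm.fn) + cm.tn / (cm.tn + cm.fp))


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, sensitivity and specificity (reduction = positive class)."""
    total = cm.tp + cm.fn + cm.tn + cm.fp
    if total == 0 or cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise ValueError("metrics need both classes in the evaluated set")
    return {
        "accuracy": (cm.tp + cm.tn) / total,
        "sensitivity": cm.tp / (cm.tp + cm.fn),
        "specificity": cm.tn / (cm.tn + cm.fp),
    }


def auc_rank(scores: np.ndarray, y: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores count one half.

    Equals the probability that a random positive outscores a random negative,
    i.e. exhaustive concordant-pair counting, and is invariant under strictly
    monotone transforms of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def stratified_folds(y: np.ndarray, k: int = 5, seed: int = 0) -> FoldPlan:
    """Seeded stratified split: per-fold positive counts within 1 of proportional."""
    y = np.asarray(y, dtype=int)
    _, counts = np.unique(y, return_counts=True)
    if len(counts) < 2 or counts.min() < k:
        raise ValueError(f"each class needs at least {k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = tuple(tuple(int(i) for i in test)
                  for _, test in skf.split(np.zeros(len(y)), y))
    return FoldPlan(folds=folds, seed=seed)


def _build_classifier(classifier: str, params: dict, seed: int):
    """RF consumes features as-is; the SVM standardizes internally.

    Scaling is fit on whatever data the estimator is fit on (so inner-CV
    training folds see only their own statistics), and the iteration cap
    guards libsvm against non-converging cells of the grid — e.g. large C on
    the near-constant dose columns.
    """
    if classifier == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    return make_pipeline(StandardScaler(),
                         SVC(random_state=seed, max_iter=200_000, **params))


def _scores_and_labels(clf, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous ranking scores for AUC plus hard class labels.

    RF scores are positive-class probabilities (labels threshold at 0.5); SVM
    scores are raw decision values (labels at the zero margin), uncalibrated
    because AUC is rank-based.
    """
    if hasattr(clf, "predict_proba"):
        scores = clf.predict_proba(X)[:, 1]
    else:
        scores = clf.decision_function(X)
    return scores, clf.predict(X)


def tune_hyperparameters(X: np.ndarray, y: np.ndarray, grid: tuple[dict, ...],
                         classifier: str, seed: int, inner_k: int = 5) -> dict:
    """Inner stratified CV: pick the grid point with highest mean balanced accuracy.

    Ties keep the first point in the grid's canonical order.
    """
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    y = np.asarray(y, dtype=int)
    _, counts = np.unique(y, return_counts=True)
    if len(counts) < 2 or counts.min() < inner_k:
        raise ValueError("inner folds would be degenerate")
    skf = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    best_params, best_ba = None, -np.inf
    for params in grid:
        bas = []
        for tr, va in splits:
            clf = _build_classifier(classifier, params, seed)
            clf.fit(X[tr], y[tr])
            cm = ConfusionMatrix.from_predictions(y[va], clf.predict(X[va]))
            bas.append(balanced_accuracy(cm))
        mean_ba = float(np.mean(bas))
        if mean_ba > best_ba:
            best_params, best_ba = params, mean_ba
    return dict(best_params)


@dataclass
class EvalReport:
    """Per-outer-fold and averaged metrics for one configuration."""

    feature_set: str
    selector: str
    classifier: str
    mode: str
    n_features: int
    seed: int
    fold_metrics: list[dict] = field(default_factory=list)

    def mean(self, metric: str) -> float:
        return float(np.mean([m[metric] for m in self.fold_metrics]))

    def summary(self) -> dict:
        out = {"feature_set": self.feature_set, "selector": self.selector,
               "classifier": self.classifier, "mode": self.mode,
               "n_features": self.n_features, "seed": self.seed}
        out |= {metric: self.mean(metric) for metric in METRICS}
        return out


def _clf_seed(seed: int) -> int:
    return (seed * 7919 + 13) % (2**31 - 1)


def _nested_reports(fm: FeatureMatrix, selector: str, classifier: str,
                    ks: list[int], mode: str, seed: int, grid: HyperGrid
                    ) -> dict[int, EvalReport]:
    """Shared engine: one outer split and one ranking pass serve every k."""
    if mode not in ("leak_free", "paper"):
        raise ValueError("mode must be 'leak_free' or 'paper'")
    max_k = max(ks)
    if max_k > len(fm.names):
        raise ValueError(f"{max_k} features requested, {len(fm.names)} available")

    plan = stratified_folds(fm.y, k=5, seed=seed)
    name_to_col = {nm: j for j, nm in enumerate(fm.names)}
    full_ranking: Ranking | None = None
    if mode == "paper":
        full_ranking = rank_features(fm, selector, seed=seed, k=max_k)

    reports = {k: EvalReport(feature_set=fm.feature_set, selector=selector,
                             classifier=classifier, mode=mode, n_features=k,
                             seed=seed) for k in ks}
    all_idx = np.arange(len(fm.y))
    for fold_no, test_idx in enumerate(plan.folds):
        test = np.asarray(test_idx)
        train = np.setdiff1d(all_idx, test)
        if mode == "paper":
            ranking = full_ranking
        else:
            fm_train = FeatureMatrix(X=fm.X[train], y=fm.y[train],
                                     names=fm.names, feature_set=fm.feature_set)
            ranking = rank_features(fm_train, selector, seed=seed + fold_no,
                                    k=max_k)
        grid_points = grid.for_classifier(classifier)
        for k in ks:
            cols = [name_to_col[nm] for nm in ranking.features[:k]]
            Xtr, Xte = fm.X[train][:, cols], fm.X[test][:, cols]
            params = tune_hyperparameters(Xtr, fm.y[train], grid_points,
                                          classifier, seed=_clf_seed(seed))
            clf = _build_classifier(classifier, params, _clf_seed(seed))
            clf.fit(Xtr, fm.y[train])
            scores, labels = _scores_and_labels(clf, Xte)
            cm = ConfusionMatrix.from_predictions(fm.y[test], labels)
            entry = {"fold": fold_no, "auc": auc_rank(scores, fm.y[test]),
                     **confusion_metrics(cm), "params": params,
                     "features": ranking.features[:k]}
            reports[k].fold_metrics.append(entry)
    return reports


def nested_cv_run(fm: FeatureMatrix, selector: str, classifier: str,
                  n_features: int, mode: str = "leak_free", seed: int = 0,
                  grid: HyperGrid | None = None) -> EvalReport:
    """Nested 5-fold CV for one (selector, classifier, feature-count) setting."""
    grid = grid or HyperGrid.default()
    return _nested_reports(fm, selector, classifier, [n_features], mode, seed,
                           grid)[n_features]


def sweep_feature_counts(fm: FeatureMatrix, selector: str, classifier: str,
                         ks: tuple[int, ...] = tuple(range(1, 11)),
                         mode: str = "leak_free", seed: int = 0,
                         grid: HyperGrid | None = None) -> list[EvalReport]:
    """Nested CV at each candidate feature count (rankings computed once)."""
    grid = grid or HyperGrid.default()
    reports = _nested_reports(fm, selector, classifier, list(ks), mode, seed,
                              grid)
    return [reports[k] for k in ks]


def representative_model(reports: list[EvalReport]) -> EvalReport:
    """The report with the highest mean AUC; ties go to fewer features."""
    if not reports:
        raise ValueError("no reports to choose from")
    return min(reports, key=lambda r: (-r.mean("auc"), r.n_features))


def run_grid(table: FeatureTable,
             selectors: tuple[str, ...] = ("chisq", "mrmr", "nca", "relieff"),
             classifiers: tuple[str, ...] = CLASSIFIERS,
             feature_sets: tuple[str, ...] = tuple(FEATURE_SETS),
             ks: tuple[int, ...] = tuple(range(1, 11)),
             mode: str = "leak_free", seed: int = 0,
             grid: HyperGrid | None = None,
             robust_features: list[str] | None = None):
    """Representative model for every feature set x selector x classifier cell.

    Returns the list of representative :class:`EvalReport` objects (one per
    cell; 7 x 4 x 2 = 56 at the defaults) and a tidy summary table with one
    row per cell and the four averaged metrics — the tabular form of the
    study-design results grid.  ``robust_features``, when given, restricts the
    radiomic columns to an ICC-robust subset before selection.
    """
    import pandas as pd

    grid = grid or HyperGrid.default()
    representatives: list[EvalReport] = []
    for fs in feature_sets:
        fm = build_feature_matrix(table, fs)
        if robust_features is not None:
            keep = [j for j, nm in enumerate(fm.names)
                    if table.groups.get(nm, "clinical").startswith("rad_") is False
                    or nm in robust_features]
            fm = FeatureMatrix(X=fm.X[:, keep], y=fm.y,
                               names=[fm.names[j] for j in keep], feature_set=fs)
        usable_ks = tuple(k for k in ks if k <= len(fm.names))
        for selector in selectors:
            for classifier in classifiers:
                reports = sweep_feature_counts(fm, selector, classifier,
                                               ks=usable_ks, mode=mode,
                                               seed=seed, grid=grid)
                representatives.append(representative_model(reports))
    summary = pd.DataFrame([r.summary() for r in representatives])
    return representatives, summary
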