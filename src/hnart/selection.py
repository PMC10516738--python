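"""Filter-type feature selection: chi-square, MRMR, NCA and ReliefF.

All four selectors rank features for a binary outcome (reduction = positive
class).  They are filters — no classifier is consulted — and each is
deterministic given its seed, so rankings are reproducible and invariant to
column order up to recorded ties.

Conventions: continuous features are quantile-binned (4 bins) for the
contingency-based scores; mutual information is estimated on the binned data
in nats; the distance-based selectors (NCA, ReliefF) require z-scored input
and the dispatcher standardizes before calling them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import FeatureTable

__all__ = [
    "FeatureMatrix",
    "Ranking",
    "build_feature_matrix",
    "standardize",
    "chisq_score",
    "mrmr_rank",
    "nca_weights",
    "relieff_rank",
    "select_top_k",
    "rank_features",
    "SELECTORS",
]

SELECTORS = ("chisq", "mrmr", "nca", "relieff")


@dataclass
class FeatureMatrix:
    """Numeric design matrix with aligned names, ready for selection/modeling."""

    X: np.ndarray
    y: np.ndarray
    names: list[str]
    feature_set: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.y):
            raise ValueError("X must be 2-D with one row per label")
        if self.X.shape[1] != len(self.names):
            raise ValueError("one name per column required")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values after imputation")
        if len(np.unique(self.y)) != 2:
            raise ValueError("labels must contain both classes")


@dataclass
class Ranking:
    """Ordered feature list with scores and the ties broken by column order."""

    method: str
    features: list[str]
    scores: list[float]
    ties: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.features) != len(self.scores):
            raise ValueError("one score per ranked feature required")


def build_feature_matrix(table: FeatureTable, feature_set: str,
                         impute: str = "median") -> FeatureMatrix:
    """Assemble one of the seven feature-set combinations as a numeric matrix.

    Patients missing a whole radiomic structure keep their row under median
    imputation, with one added missingness-indicator column per affected
    structure; ``impute="complete"`` drops incomplete rows instead.
    """
    names = table.feature_names(feature_set)
    sub = table.df[names].copy()
    y = table.labels

    if impute == "complete":
        keep = ~sub.isna().any(axis=1)
        sub, y = sub[keep], y[keep.to_numpy()]
    elif impute == "median":
        for structure in ("gtvp", "gtvn"):
            block = [c for c in names if table.groups[c] == f"rad_{structure}"]
            if block and sub[block].isna().any().any():
                sub[f"{structure}_missing"] = sub[block[0]].isna().astype(int)
        med = sub.median()
        sub = sub.fillna(med.fillna(0.0))
    else:
        raise ValueError("impute must be 'median' or 'complete'")
    return FeatureMatrix(X=sub.to_numpy(dtype=float), y=y,
                         names=list(sub.columns), feature_set=feature_set)


def standardize(X: np.ndarray) -> np.ndarray:
    """Column z-score; constant columns map to zero."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    out = np.zeros_like(X)
    nz = sd > 0
    out[:, nz] = (X[:, nz] - mu[nz]) / sd[nz]
    return out


def _order_with_ties(scores: np.ndarray, names: list[str]
                     ) -> tuple[list[int], list[tuple[str, str]]]:
    """Descending score order, ties broken by original column index."""
    order = sorted(range(len(scores)), key=lambda j: (-scores[j], j))
    ties = [(names[order[i]], names[order[i + 1]])
            for i in range(len(order) - 1)
            if scores[order[i]] == scores[order[i + 1]]]
    return order, ties


def _bin_column(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Integer codes: native categories for discrete columns, quantile bins else."""
    uniq = np.unique(x)
    if len(uniq) <= n_bins:
        return np.searchsorted(uniq, x)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    table = np.zeros((a.max() + 1, b.max() + 1))
    np.add.at(table, (a, b), 1.0)
    return table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]


def chisq_score(X: np.ndarray, y: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Pearson chi-square statistic of each feature's bin x class table.

    Constant features (a single occupied bin) score 0: they cannot separate
    the classes, but they are not an error.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        table = _contingency(_bin_column(X[:, j], n_bins), y)
        if table.shape[0] < 2 or table.shape[1] < 2:
            continue
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        scores[j] = float(np.sum((table - expected) ** 2 / expected))
    return scores


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in MI (nats) between two integer-coded variables."""
    table = _contingency(a, b)
    p = table / table.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def mrmr_rank(X: np.ndarray, y: np.ndarray, k: int, n_bins: int = 4,
              names: list[str] | None = None) -> Ranking:
    """Minimum-redundancy maximum-relevance greedy forward ranking.

    Uses the mutual-information difference (MID) criterion: at each step pick
    the unselected feature maximizing I(f; y) minus the mean I(f; s) over
    already-selected features s, with MI estimated on 4-bin quantile-coded
    data.  Ties go to the earlier column.  The returned scores are the MID
    values at the step each feature was chosen.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if k > p:
        raise ValueError(f"cannot rank {k} of {p} features")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    names = names if names is not None else [f"f{j}" for j in range(p)]

    codes = [_bin_column(X[:, j], n_bins) for j in range(p)]
    y = np.asarray(y, dtype=int)
    relevance = np.array([_mutual_information(c, y) for c in codes])

    selected: list[int] = []
    scores: list[float] = []
    ties: list[tuple[str, str]] = []
    redundancy = np.zeros(p)
    remaining = list(range(p))
    for _ in range(k):
        if selected:
            crit = relevance - redundancy / len(selected)
        else:
            crit = relevance.copy()
        crit_rem = [(float(crit[j]), j) for j in remaining]
        best = max(crit_rem, key=lambda t: (t[0], -t[1]))
        tied = [j for v, j in crit_rem if v == best[0] and j != best[1]]
        ties.extend((names[best[1]], names[j]) for j in tied)
        j_best = best[1]
        selected.append(j_best)
        scores.append(best[0])
        remaining.remove(j_best)
        for j in remaining:
            redundancy[j] += _mutual_information(codes[j], codes[j_best])
    return Ranking(method="mrmr", features=[names[j] for j in selected],
                   scores=scores, ties=ties)


def nca_weights(X: np.ndarray, y: np.ndarray, lam: float | None = None,
                step: float = 0.1, iters: int = 100, seed: int = 0,
                names: list[str] | None = None
                ) -> tuple[np.ndarray, Ranking]:
    """Neighborhood-component-analysis feature weights for selection.

    Learns non-negative per-feature weights ``w`` by gradient ascent on the
    leave-one-out soft-neighbor objective

        F(w) = sum_i sum_{j != i, y_j = y_i} p_ij  -  lambda * sum_r w_r^2,
        p_ij proportional to exp(-d_w(i, j)),
        d_w(i, j) = sum_r w_r^2 |x_ir - x_jr| / sigma,

    where ``sigma`` fixes the kernel width to the mean initial distance.
    Expects z-scored input (rejected otherwise), ``lambda`` defaults to 1/n,
    and the step is halved whenever an update fails to improve F.  Ranking is
    by descending weight magnitude.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    sd = X.std(axis=0)
    if np.any((np.abs(sd - 1.0) > 0.2) & (sd > 0)):
        raise ValueError("NCA expects z-scored features; standardize upstream")
    names = names if names is not None else [f"f{j}" for j in range(p)]
    lam = 1.0 / n if lam is None else lam

    rng = np.random.default_rng(seed)
    w = np.abs(1.0 + 0.01 * rng.standard_normal(p))
    dabs = np.abs(X[:, None, :] - X[None, :, :])  # (n, n, p)
    same = (y[:, None] == y[None, :]) & ~np.eye(n, dtype=bool)

    sigma = float(np.mean(dabs.sum(axis=2)))
    sigma = max(sigma, 1e-12)
    dabs = dabs / sigma

    def objective_and_grad(w: np.ndarray) -> tuple[float, np.ndarray]:
        d = dabs @ (w**2)
        np.fill_diagonal(d, np.inf)
        k = np.exp(-(d - d.min(axis=1, keepdims=True)))  # row-shift for stability
        np.fill_diagonal(k, 0.0)
        pij = k / k.sum(axis=1, keepdims=True)
        p_i = (pij * same).sum(axis=1)
        obj = float(p_i.sum()) - lam * float(np.sum(w**2))
        pull = np.einsum("ij,ijr->r", pij * p_i[:, None], dabs)
        push = np.einsum("ij,ijr->r", pij * same, dabs)
        grad = 2.0 * w * (pull - push) - 2.0 * lam * w
        return obj, grad

    obj, grad = objective_and_grad(w)
    alpha = step
    for _ in range(iters):
        w_new = np.maximum(w + alpha * grad, 0.0)
        obj_new, grad_new = objective_and_grad(w_new)
        if obj_new > obj:
            w, obj, grad = w_new, obj_new, grad_new
            alpha *= 1.05
        else:
            alpha *= 0.5
            if alpha < 1e-8:
                break

    weights = np.abs(w)
    order, ties = _order_with_ties(weights, names)
    ranking = Ranking(method="nca", features=[names[j] for j in order],
                      scores=[float(weights[j]) for j in order], ties=ties)
    return weights, ranking


def relieff_rank(X: np.ndarray, y: np.ndarray, k_neighbors: int = 10,
                 names: list[str] | None = None) -> Ranking:
    """ReliefF scores for binary classification, deterministic (all instances).

    For every instance the k nearest hits (same class) and k nearest misses
    (other class) are found by Euclidean distance on the standardized
    features; each feature's score accumulates miss-difference minus
    hit-difference, normalized by the feature range and by n * k.  Constant
    features score exactly 0.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if np.any(counts < k_neighbors + 1):
        raise ValueError(
            f"every class needs more than {k_neighbors} members for "
            f"{k_neighbors}-neighbor ReliefF")
    names = names if names is not None else [f"f{j}" for j in range(p)]

    rng_span = X.max(axis=0) - X.min(axis=0)
    rng_span[rng_span == 0] = 1.0
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)

    scores = np.zeros(p)
    for i in range(n):
        hits = np.where(y == y[i])[0]
        misses = np.where(y != y[i])[0]
        hits = hits[hits != i]
        nh = hits[np.argsort(d2[i, hits], kind="stable")[:k_neighbors]]
        nm = misses[np.argsort(d2[i, misses], kind="stable")[:k_neighbors]]
        scores += np.abs(X[nm] - X[i]).sum(axis=0) / rng_span
        scores -= np.abs(X[nh] - X[i]).sum(axis=0) / rng_span
    scores /= n * k_neighbors

    order, ties = _order_with_ties(scores, names)
    return Ranking(method="relieff", features=[names[j] for j in order],
                   scores=[float(scores[j]) for j in order], ties=ties)


def select_top_k(ranking: Ranking, k: int = 10) -> list[str]:
    """First k features of a ranking (ties were already broken by column order)."""
    if k > len(ranking.features):
        raise ValueError(f"requested top {k} of {len(ranking.features)} features")
    return ranking.features[:k]


def rank_features(fm: FeatureMatrix, method: str, seed: int = 0,
                  k: int | None = None) -> Ranking:
    """Dispatch to one selector; handles standardization for NCA/ReliefF.

    ``k`` bounds the greedy MRMR depth (defaults to all features); the
    score-based selectors always rank every feature.
    """
    if method not in SELECTORS:
        raise ValueError(f"unknown selector {method!r}; pick from {SELECTORS}")
    X, y, names = fm.X, fm.y, fm.names
    if method == "chisq":
        scores = chisq_score(X, y)
        order, ties = _order_with_ties(scores, names)
        return Ranking(method="chisq", features=[names[j] for j in order],
                       scores=[float(scores[j]) for j in order], ties=ties)
    if method == "mrmr":
        return mrmr_rank(X, y, k=k or len(names), names=names)
    if method == "nca":
        _, ranking = nca_weights(standardize(X), y, seed=seed, names=names)
        return ranking
    return relieff_rank(standardize(X), y, names=names)
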