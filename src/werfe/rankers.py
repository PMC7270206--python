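"""Per-gene importance scores.

Two model-derived rankers drive recursive elimination (squared linear-SVM
weights, random-forest impurity importances) and two filter statistics
(two-class Fisher score, ReliefF) serve as ranking baselines for the
incremental search method.  Higher score always means more important, and
every score-based ordering breaks ties by original gene order (stable
sort) for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dataset import ExpressionDataset
from .errors import ConfigError, DataValidationError

__all__ = [
    "ImportanceScores",
    "svm_weight_scores",
    "rf_importance_scores",
    "fisher_scores",
    "relieff_scores",
    "make_ranker",
    "register_ranker",
    "ranker_names",
]

#: Guard added to the Fisher-score denominator so genes that are constant
#: within both classes do not divide by zero.
FISHER_EPS = 1e-12


@dataclass
class ImportanceScores:
    """One finite real score per gene; higher = more important."""

    gene_ids: list[str]
    scores: np.ndarray
    ranker_name: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.gene_ids) != self.scores.shape[0]:
            raise DataValidationError(
                f"{len(self.gene_ids)} gene identifiers for {self.scores.shape[0]} scores"
            )
        if not np.isfinite(self.scores).all():
            raise DataValidationError(f"non-finite score from ranker {self.ranker_name!r}")

    def ranking(self) -> list[str]:
        """Gene identifiers in descending-score order, stable within ties."""
        order = np.argsort(-self.scores, kind="stable")
        return [self.gene_ids[i] for i in order]


def _require_two_classes(data: ExpressionDataset, min_per_class: int = 1) -> None:
    n0, n1 = data.class_counts()
    if n0 < min_per_class or n1 < min_per_class:
        raise DataValidationError(
            f"need at least {min_per_class} samples per class, got {n0}/{n1}"
        )


def svm_weight_scores(
    train: ExpressionDataset, C: float = 1.0, standardize: bool = True
) -> ImportanceScores:
    """Squared coefficients w_j^2 of a linear-kernel SVM fitted on `train`.

    The squared weight is the classical SVM-RFE elimination criterion: the
    magnitude of a gene's contribution to the separating hyperplane,
    sign-free.  Standardization (fit on the training data only) is on by
    default so that raw expression ranges do not dominate the margin.
    """
    if C <= 0:
        raise ConfigError(f"SVM penalty C must be positive, got {C}")
    _require_two_classes(train, min_per_class=2)
    X = train.matrix
    if standardize:
        X = StandardScaler().fit_transform(X)
    svm = SVC(kernel="linear", C=C)
    svm.fit(X, train.labels)
    w = np.asarray(svm.coef_).ravel()
    return ImportanceScores(list(train.gene_ids), w**2, "svm")


def rf_importance_scores(
    train: ExpressionDataset, n_trees: int = 500, seed: int = 0
) -> ImportanceScores:
    """Impurity-based variable importances of a seeded random forest."""
    if n_trees < 1:
        raise ConfigError(f"n_trees must be a positive integer, got {n_trees}")
    _require_two_classes(train)
    rf = RandomForestClassifier(n_estimators=int(n_trees), random_state=int(seed))
    rf.fit(train.matrix, train.labels)
    return ImportanceScores(list(train.gene_ids), rf.feature_importances_, "rf")


def fisher_scores(data: ExpressionDataset) -> ImportanceScores:
    """Two-class Fisher score per gene.

    score_j = (n0 (mu0_j - mu_j)^2 + n1 (mu1_j - mu_j)^2)
              / (n0 var0_j + n1 var1_j + eps)

    with class-conditional means/variances (population variances) and a
    small epsilon guarding zero pooled within-class variance.
    """
    _require_two_classes(data, min_per_class=2)
    X, y = data.matrix, data.labels
    mu = X.mean(axis=0)
    between = np.zeros(data.n_genes)
    within = np.zeros(data.n_genes)
    for cls in (0, 1):
        Xc = X[y == cls]
        nc = Xc.shape[0]
        between += nc * (Xc.mean(axis=0) - mu) ** 2
        within += nc * Xc.var(axis=0)
    return ImportanceScores(list(data.gene_ids), between / (within + FISHER_EPS), "fisher")


def relieff_scores(
    data: ExpressionDataset,
    k_neighbors: int = 10,
    n_probes: int | None = None,
    seed: int | None = None,
) -> ImportanceScores:
    """ReliefF feature weights for two classes.

    Features are min-max scaled to [0, 1]; for each probe sample the weight
    of gene j decreases by its mean absolute difference to the k nearest
    same-class neighbours (hits) and increases by its mean difference to
    the k nearest other-class neighbours (misses), averaged over probes.
    Distances are Manhattan on the scaled features.  With two classes the
    prior reweighting of misses reduces to 1.  By default every sample is
    a probe, which makes the weights deterministic.
    """
    n0, n1 = data.class_counts()
    if k_neighbors < 1:
        raise ConfigError(f"k_neighbors must be positive, got {k_neighbors}")
    if k_neighbors >= min(n0, n1):
        raise DataValidationError(
            f"k_neighbors={k_neighbors} must be smaller than the smaller class ({min(n0, n1)})"
        )
    X, y = data.matrix, data.labels
    m = data.n_samples

    lo, hi = X.min(axis=0), X.max(axis=0)
    span = hi - lo
    scaled = np.zeros_like(X)
    nonconst = span > 0
    scaled[:, nonconst] = (X[:, nonconst] - lo[nonconst]) / span[nonconst]

    if n_probes is None or n_probes >= m:
        probes = np.arange(m)
    else:
        rng = np.random.default_rng(seed)
        probes = rng.choice(m, size=int(n_probes), replace=False)

    dist = cdist(scaled, scaled, metric="cityblock")
    weights = np.zeros(data.n_genes)
    for i in probes:
        same = np.flatnonzero(y == y[i])
        same = same[same != i]
        other = np.flatnonzero(y != y[i])
        hits = same[np.argsort(dist[i, same], kind="stable")[:k_neighbors]]
        misses = other[np.argsort(dist[i, other], kind="stable")[:k_neighbors]]
        weights += np.abs(scaled[misses] - scaled[i]).mean(axis=0)
        weights -= np.abs(scaled[hits] - scaled[i]).mean(axis=0)
    weights /= len(probes)
    return ImportanceScores(list(data.gene_ids), weights, "relieff")


# -- name-based registry (used by the RFE engine, ISM and the CLI) ---------


def _svm_ranker(train, seed, **params):
    return svm_weight_scores(train, **params)


def _rf_ranker(train, seed, **params):
    return rf_importance_scores(train, seed=seed, **params)


def _fisher_ranker(train, seed, **params):
    return fisher_scores(train, **params)


def _relieff_ranker(train, seed, **params):
    return relieff_scores(train, seed=seed, **params)


_REGISTRY = {
    "svm": _svm_ranker,
    "rf": _rf_ranker,
    "fisher": _fisher_ranker,
    "relieff": _relieff_ranker,
}


def register_ranker(name: str, fn) -> None:
    """Register ``fn(train, seed, **params) -> ImportanceScores`` under `name`."""
    _REGISTRY[name] = fn


def ranker_names() -> list[str]:
    return sorted(_REGISTRY)


def make_ranker(name: str, **params):
    """Bind a registered ranker's parameters into a ``f(train, seed)`` callable."""
    try:
        fn = _REGISTRY[name]
    except KeyError:
        raise ConfigError(f"unknown ranker {name!r}; registered: {ranker_names()}") from None

    def ranker(train: ExpressionDataset, seed: int = 0) -> ImportanceScores:
        return fn(train, seed, **params)

    ranker.__name__ = name
    return ranker
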