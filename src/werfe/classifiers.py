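"""Base-learner registry.

Two learners drive both elimination and evaluation: a linear-kernel SVM
(features standardized inside the pipeline, so scaling parameters are
learned on the training split only) and a random forest.  Additional
classifiers can be registered by name, so any estimator with the sklearn
fit/predict interface (e.g. a gradient-boosting machine) can be plugged in
for evaluation without touching the selection code.
"""

from __future__ import annotations

from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigError

__all__ = ["make_classifier", "register_classifier", "decision_scores", "classifier_names"]


def _make_svm(seed: int, C: float = 1.0, standardize: bool = True):
    if C <= 0:
        raise ConfigError(f"SVM penalty C must be positive, got {C}")
    svm = SVC(kernel="linear", C=C)
    if standardize:
        return Pipeline([("scale", StandardScaler()), ("svm", svm)])
    return svm


def _make_rf(seed: int, n_trees: int = 500):
    if n_trees < 1:
        raise ConfigError(f"n_trees must be a positive integer, got {n_trees}")
    return RandomForestClassifier(n_estimators=int(n_trees), random_state=int(seed))


_REGISTRY = {"svm": _make_svm, "rf": _make_rf}


def register_classifier(name: str, factory) -> None:
    """Register ``factory(seed, **params) -> estimator`` under `name`."""
    _REGISTRY[name] = factory


def classifier_names() -> list[str]:
    return sorted(_REGISTRY)


def make_classifier(name: str, seed: int = 0, **params):
    """Instantiate a registered classifier by name."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise ConfigError(
            f"unknown classifier {name!r}; registered: {classifier_names()}"
        ) from None
    return factory(seed, **params)


def decision_scores(fitted, X):
    """Continuous class-1 scores: SVM margin or class probability."""
    if hasattr(fitted, "decision_function"):
        return fitted.decision_function(X)
    return fitted.predict_proba(X)[:, 1]


def importance_from_fitted(name: str, fitted):
    """Per-feature importances of an already-fitted registered classifier.

    Used by the elimination engine so one trained model per step yields
    both the step accuracy and the gene weights: squared hyperplane
    coefficients for the linear SVM, impurity importances for the forest.
    Returns None when `name` exposes no importances.
    """
    est = fitted
    if isinstance(fitted, Pipeline):
        est = fitted[-1]
    if name == "svm":
        import numpy as np

        return np.asarray(est.coef_).ravel() ** 2
    if name == "rf":
        return est.feature_importances_
    return None
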