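"""Seeded cross-validated evaluation of a candidate gene subset.

The threshold sweep, the incremental search and the final report all score
a subset the same way: stratified k-fold CV of an evaluation classifier on
the full dataset restricted to the subset, with predictions (and
continuous scores) pooled out-of-fold into one confusion matrix / ROC.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifiers import decision_scores, make_classifier
from .dataset import ExpressionDataset
from .errors import DataValidationError
from .metrics import MetricsReport, confusion_metrics, roc_curve_auc

__all__ = ["cross_val_predictions", "evaluate_subset", "derive_seed", "stratified_folds"]

_SEED_MOD = 2**31 - 1


def derive_seed(master: int, *streams: int) -> int:
    """Deterministic child seed below 2^31 for one (fold, component) stream."""
    state = np.random.SeedSequence([int(master) % _SEED_MOD, *[int(s) for s in streams]])
    return int(state.generate_state(1)[0] % _SEED_MOD)


def stratified_folds(data: ExpressionDataset, k: int, seed: int):
    """Seeded stratified fold assignment as (train_idx, test_idx) pairs."""
    n0, n1 = data.class_counts()
    if k < 2:
        raise DataValidationError(f"fold count must be >= 2, got {k}")
    if min(n0, n1) < k:
        raise DataValidationError(
            f"cannot build {k} stratified folds with class counts {n0}/{n1}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % _SEED_MOD)
    return list(skf.split(data.matrix, data.labels))


def cross_val_predictions(
    data: ExpressionDataset,
    gene_ids,
    classifier: str,
    k_eval: int,
    seed: int,
    classifier_params: dict | None = None,
):
    """Pooled out-of-fold labels, hard predictions and continuous scores."""
    sub = data.subset_genes(gene_ids)
    y_pred = np.empty(sub.n_samples, dtype=int)
    y_score = np.empty(sub.n_samples, dtype=float)
    for fold, (tr, te) in enumerate(stratified_folds(sub, k_eval, seed)):
        clf = make_classifier(
            classifier, seed=derive_seed(seed, fold), **(classifier_params or {})
        )
        clf.fit(sub.matrix[tr], sub.labels[tr])
        y_pred[te] = clf.predict(sub.matrix[te])
        y_score[te] = decision_scores(clf, sub.matrix[te])
    return sub.labels, y_pred, y_score


def evaluate_subset(
    data: ExpressionDataset,
    gene_ids,
    classifier: str,
    k_eval: int,
    seed: int,
    classifier_params: dict | None = None,
    with_roc: bool = False,
) -> MetricsReport:
    """Cross-validated Sen/Spe/Acc (and optionally ROC/AUC) of one subset."""
    y_true, y_pred, y_score = cross_val_predictions(
        data, gene_ids, classifier, k_eval, seed, classifier_params
    )
    report = confusion_metrics(y_true, y_pred)
    if with_roc:
        roc = roc_curve_auc(y_true, y_score)
        report.auc = roc.auc
        report.roc_points = roc.roc_points
        report.roc_thresholds = roc.roc_thresholds
    return report
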