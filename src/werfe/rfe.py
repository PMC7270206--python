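"""The recursive-feature-elimination engine.

Starting from the full gene set, each step fits a classifier on the
surviving genes of the training split, records its accuracy on the test
split, ranks the surviving genes with the chosen importance ranker (fitted
on the training split only), and removes the ``s`` lowest-scored genes
(stable tie-break by original gene order).  The loop stops once removing
``s`` more genes would empty the set, so the last evaluated subset has
between 1 and ``s`` genes.  The best subset is the trajectory entry with
the highest test accuracy; accuracy ties go to the smaller subset, since
a compact gene set is the point of the exercise.

Note that, as specified by the selection procedure, the per-step accuracy
is computed on the same held-out fold that later picks the best subset —
the selected subset is therefore tuned on that fold.  This is inherent to
the wrapper design; the ensemble stage mitigates it by pooling selections
across folds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .classifiers import importance_from_fitted, make_classifier
from .dataset import ExpressionDataset
from .errors import ConfigError, DataValidationError
from .evaluation import derive_seed
from .metrics import confusion_metrics
from .rankers import ImportanceScores, make_ranker

__all__ = ["RfeStep", "RfeTrajectory", "RfeResult", "rfe_select", "default_step_size"]

logger = logging.getLogger(__name__)


@dataclass
class RfeStep:
    """One elimination step: the surviving genes and their test accuracy."""

    gene_ids: tuple[str, ...]
    accuracy: float  # percent, on the test split
    index: int


@dataclass
class RfeTrajectory:
    """Ordered record of surviving subsets across elimination steps."""

    steps: list[RfeStep]
    step_size: int
    ranker_name: str

    def sizes(self) -> list[int]:
        return [len(s.gene_ids) for s in self.steps]

    def accuracies(self) -> list[float]:
        return [s.accuracy for s in self.steps]


@dataclass
class RfeResult:
    """Best subset of one RFE run plus the full trajectory behind it."""

    best_subset: tuple[str, ...]
    best_accuracy: float
    trajectory: RfeTrajectory


def default_step_size(n_genes: int) -> int:
    """s = 1 for small panels; for large ones, bound the run at ~100 refits."""
    return 1 if n_genes <= 500 else math.ceil(n_genes / 100)


def rfe_select(
    train: ExpressionDataset,
    test: ExpressionDataset,
    ranker,
    classifier: str = "svm",
    s: int | None = None,
    seed: int = 0,
    ranker_params: dict | None = None,
    classifier_params: dict | None = None,
) -> RfeResult:
    """Run recursive feature elimination on one train/test split.

    Parameters
    ----------
    train, test
        Datasets sharing the same genes in the same order.
    ranker
        Registered ranker name ("svm", "rf", "fisher", "relieff") or a
        callable ``f(train, seed) -> ImportanceScores``.
    classifier
        Registered classifier evaluated at every step.
    s
        Number of genes removed per step; defaults per
        :func:`default_step_size`.
    seed
        Master seed; per-step learner seeds are derived from it.
    """
    if train.gene_ids != test.gene_ids:
        raise DataValidationError("train and test must share gene_ids in the same order")
    if train.n_genes == 0:
        raise DataValidationError("empty initial gene set")
    if s is None:
        s = default_step_size(train.n_genes)
    if s < 1:
        raise ConfigError(f"elimination step size s must be >= 1, got {s}")

    if callable(ranker):
        rank_fn = ranker
        ranker_name = getattr(ranker, "__name__", "custom")
        reuse_fit = False
    else:
        rank_fn = make_ranker(ranker, **(ranker_params or {}))
        ranker_name = ranker
        # when the ranker is the step classifier itself (same family, same
        # parameters), the one trained model supplies both the accuracy
        # and the gene weights — no second fit
        reuse_fit = ranker == classifier and (ranker_params or {}) == (
            classifier_params or {}
        )

    if len(set(test.labels.tolist())) < 2:
        logger.warning(
            "test split contains a single class; accuracy is defined but "
            "sensitivity or specificity is degenerate"
        )

    surviving = list(train.gene_ids)
    steps: list[RfeStep] = []
    step_index = 0
    while True:
        sub_train = train.subset_genes(surviving)
        sub_test = test.subset_genes(surviving)
        clf = make_classifier(
            classifier, seed=derive_seed(seed, step_index, 0), **(classifier_params or {})
        )
        clf.fit(sub_train.matrix, sub_train.labels)
        acc = confusion_metrics(sub_test.labels, clf.predict(sub_test.matrix)).accuracy
        steps.append(RfeStep(gene_ids=tuple(surviving), accuracy=acc, index=step_index))

        if len(surviving) <= s:
            break
        if reuse_fit:
            score_values = importance_from_fitted(classifier, clf)
        else:
            score_values = None
        if score_values is None:
            score_values = np.asarray(
                rank_fn(sub_train, derive_seed(seed, step_index, 1)).scores
            )
        drop = np.argsort(score_values, kind="stable")[:s]
        dropped = {surviving[i] for i in drop}
        surviving = [g for g in surviving if g not in dropped]
        step_index += 1

    best = steps[0]
    for step in steps[1:]:
        # later steps are strictly smaller, so >= implements the
        # smallest-subset tie-break
        if step.accuracy >= best.accuracy:
            best = step
    trajectory = RfeTrajectory(steps=steps, step_size=s, ranker_name=ranker_name)
    return RfeResult(
        best_subset=best.gene_ids, best_accuracy=best.accuracy, trajectory=trajectory
    )
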