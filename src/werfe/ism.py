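"""Incremental search over a ranked gene list.

Baseline subset-selection for filter rankers (Fisher score, ReliefF):
grow nested prefix subsets of the ranking at sizes theta, theta + step,
theta + 2*step, ... capped at n (the full list is always evaluated, so
the no-selection baseline is in the search space), score each prefix by
seeded stratified CV, and keep the most accurate; accuracy ties go to the
smaller prefix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .errors import ConfigError
from .evaluation import evaluate_subset
from .rankers import ImportanceScores

__all__ = ["IsmRow", "IsmResult", "ism_select", "ism_sizes"]


@dataclass
class IsmRow:
    size: int
    gene_ids: tuple[str, ...]
    accuracy: float
    sensitivity: float
    specificity: float


@dataclass
class IsmResult:
    rows: list[IsmRow]
    best: IsmRow

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": [r.size for r in self.rows],
                "accuracy_pct": [r.accuracy for r in self.rows],
                "sensitivity_pct": [r.sensitivity for r in self.rows],
                "specificity_pct": [r.specificity for r in self.rows],
            }
        )


def ism_sizes(n: int, theta: int, step: int) -> list[int]:
    """The arithmetic size grid theta, theta+step, ... capped at n."""
    if theta < 1 or theta > n:
        raise ConfigError(f"theta must lie in [1, {n}], got {theta}")
    if step < 1:
        raise ConfigError(f"step must be >= 1, got {step}")
    sizes = list(range(theta, n + 1, step))
    if sizes[-1] != n:
        sizes.append(n)
    return sizes


def _ranking_ids(ranking) -> list[str]:
    if isinstance(ranking, ImportanceScores):
        return ranking.ranking()
    if hasattr(ranking, "gene_ids"):  # RankedGeneList
        return list(ranking.gene_ids)
    return list(ranking)


def ism_select(
    data: ExpressionDataset,
    ranking,
    theta: int = 10,
    step: int = 10,
    eval_classifier: str = "svm",
    k_eval: int = 10,
    seed: int = 0,
    eval_params: dict | None = None,
) -> IsmResult:
    """Evaluate nested prefixes of `ranking` and keep the most accurate.

    `ranking` may be an :class:`~werfe.rankers.ImportanceScores` (converted
    to descending-score order with stable ties), a ranked gene list, or a
    plain sequence of gene identifiers.
    """
    ordered = _ranking_ids(ranking)
    rows: list[IsmRow] = []
    for size in ism_sizes(len(ordered), theta, step):
        subset = tuple(ordered[:size])
        rep = evaluate_subset(data, subset, eval_classifier, k_eval, seed, eval_params)
        rows.append(IsmRow(size, subset, rep.accuracy, rep.sensitivity, rep.specificity))
    best = rows[0]
    for row in rows[1:]:
        if row.accuracy > best.accuracy:  # strict: ties keep the smaller prefix
            best = row
    return IsmResult(rows=rows, best=best)
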