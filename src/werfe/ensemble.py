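"""Ensemble wrapper gene selection by vote pooling.

The algorithm runs N independent RFE selectors inside one k-fold
stratified cross-validation: in each fold every selector picks its best
gene subset on the shared train/test split, all k x N subsets are pooled,
and each gene's vote t_f counts the pooled subsets containing it (a gene
selected by both selectors in a fold earns two votes that fold, so votes
range from 0 to k x N).  Genes are ranked by votes, and the final subset
is chosen by sweeping the threshold t_0 from 0 to k x N - 1: the candidate
at t_0 is the set of genes with t_f > t_0, each candidate is scored by
seeded stratified CV of an evaluation classifier, and the most accurate
candidate wins (accuracy ties go to the larger t_0, i.e. the smaller
subset).

The user-facing surface is the :class:`WERFE` model object whose
:meth:`WERFE.fit` returns a :class:`WERFEResults`; the stage functions
(:func:`ensemble_vote`, :func:`rank_by_votes`, :func:`threshold_sweep`)
are also public for piecewise use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .errors import ConfigError, DataValidationError
from .evaluation import derive_seed, evaluate_subset, stratified_folds
from .metrics import MetricsReport
from .rfe import RfeResult, rfe_select

__all__ = [
    "Selector",
    "VoteTable",
    "RankedGeneList",
    "SweepRow",
    "SweepResult",
    "ensemble_vote",
    "rank_by_votes",
    "threshold_sweep",
    "WERFE",
    "WERFEResults",
    "default_selectors",
]

logger = logging.getLogger(__name__)


@dataclass
class Selector:
    """One base RFE selector: an importance ranker plus a step classifier."""

    ranker: str = "svm"
    classifier: str = "svm"
    s: int | None = None
    ranker_params: dict = field(default_factory=dict)
    classifier_params: dict = field(default_factory=dict)
    name: str | None = None

    def __post_init__(self) -> None:
        if self.name is None:
            self.name = f"{self.ranker}rfe"

    def select(self, train: ExpressionDataset, test: ExpressionDataset, seed: int) -> RfeResult:
        return rfe_select(
            train,
            test,
            ranker=self.ranker,
            classifier=self.classifier,
            s=self.s,
            seed=seed,
            ranker_params=self.ranker_params,
            classifier_params=self.classifier_params,
        )


def default_selectors(
    s: int | None = None, n_trees: int = 500, C: float = 1.0
) -> list[Selector]:
    """The default N=2 ensemble: SVM-RFE and RF-RFE."""
    return [
        Selector("svm", "svm", s=s, ranker_params={"C": C}, classifier_params={"C": C}),
        Selector(
            "rf",
            "rf",
            s=s,
            ranker_params={"n_trees": n_trees},
            classifier_params={"n_trees": n_trees},
        ),
    ]


@dataclass
class VoteTable:
    """Per-gene vote counts over all fold x selector best subsets."""

    gene_ids: list[str]
    votes: np.ndarray
    k_folds: int
    n_selectors: int

    def __post_init__(self) -> None:
        self.votes = np.asarray(self.votes, dtype=int)
        if self.votes.shape[0] != len(self.gene_ids):
            raise DataValidationError("votes and gene_ids length mismatch")
        if (self.votes < 0).any() or (self.votes > self.max_votes).any():
            raise DataValidationError(
                f"vote counts must lie in [0, {self.max_votes}]"
            )

    @property
    def max_votes(self) -> int:
        return self.k_folds * self.n_selectors

    def total_votes(self) -> int:
        return int(self.votes.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_ids, "votes": self.votes})


@dataclass
class RankedGeneList:
    """Genes in descending-vote order, original order within vote ties."""

    gene_ids: list[str]
    votes: np.ndarray

    def __post_init__(self) -> None:
        self.votes = np.asarray(self.votes, dtype=int)
        if np.any(np.diff(self.votes) > 0):
            raise DataValidationError("votes must be non-increasing down the ranking")

    def top(self, n: int) -> list[str]:
        return self.gene_ids[:n]


@dataclass
class SweepRow:
    """One threshold of the sweep: genes with votes strictly above t0."""

    t0: int
    gene_ids: tuple[str, ...]
    size: int
    accuracy: float
    sensitivity: float
    specificity: float


@dataclass
class SweepResult:
    """The full t0 sweep and the accuracy-maximizing choice."""

    rows: list[SweepRow]
    chosen_t0: int
    final_subset: tuple[str, ...]
    eval_classifier: str

    def to_frame(self) -> pd.DataFrame:
        max_tf = len(self.rows)  # thresholds run 0 .. kN-1, votes reach kN
        return pd.DataFrame(
            {
                "t0": [r.t0 for r in self.rows],
                "tf_range": [f"{r.t0 + 1}-{max_tf}" for r in self.rows],
                "gene_number": [r.size for r in self.rows],
                "accuracy_pct": [r.accuracy for r in self.rows],
                "sensitivity_pct": [r.sensitivity for r in self.rows],
                "specificity_pct": [r.specificity for r in self.rows],
            }
        )


def ensemble_vote(
    data: ExpressionDataset,
    selectors: list[Selector],
    k: int = 10,
    seed: int = 0,
    return_fold_subsets: bool = False,
):
    """Pool per-fold best subsets of every selector into a vote table.

    All selectors see identical stratified fold splits.  Returns the
    :class:`VoteTable`, and optionally the list of (fold, selector_name,
    best_subset) records behind it.
    """
    if not selectors:
        raise ConfigError("selector list must not be empty")
    folds = stratified_folds(data, k, seed)
    votes = {g: 0 for g in data.gene_ids}
    fold_subsets: list[tuple[int, str, tuple[str, ...]]] = []
    for fold, (tr, te) in enumerate(folds):
        train = data.take_samples(tr)
        test = data.take_samples(te)
        for j, selector in enumerate(selectors):
            result = selector.select(train, test, seed=derive_seed(seed, fold, j))
            for g in result.best_subset:
                votes[g] += 1
            fold_subsets.append((fold, selector.name, result.best_subset))
            logger.info(
                "fold %d selector %s: best subset of %d genes at %.2f%% accuracy",
                fold,
                selector.name,
                len(result.best_subset),
                result.best_accuracy,
            )
    table = VoteTable(
        gene_ids=list(data.gene_ids),
        votes=np.array([votes[g] for g in data.gene_ids]),
        k_folds=k,
        n_selectors=len(selectors),
    )
    if return_fold_subsets:
        return table, fold_subsets
    return table


def rank_by_votes(table: VoteTable) -> RankedGeneList:
    """Descending vote order, stable within ties (canonical gene order)."""
    order = np.argsort(-table.votes, kind="stable")
    return RankedGeneList(
        gene_ids=[table.gene_ids[i] for i in order], votes=table.votes[order]
    )


def threshold_sweep(
    data: ExpressionDataset,
    table: VoteTable,
    eval_classifier: str = "svm",
    k_eval: int = 10,
    seed: int = 0,
    eval_params: dict | None = None,
    max_genes: int | None = None,
) -> SweepResult:
    """Sweep the vote threshold t0 and pick the most accurate subset.

    For every t0 in [0, kN-1] the candidate subset holds the genes with
    votes > t0 (listed in ranked order); nonempty candidates are scored by
    seeded stratified ``k_eval``-fold CV of `eval_classifier` on the full
    dataset restricted to the candidate.  Empty candidates get NaN
    metrics.  Ties in accuracy resolve to the larger t0 (smaller subset);
    `max_genes`, when set, restricts the choice to candidates at most that
    large.
    """
    if len(table.gene_ids) == 0:
        raise DataValidationError("empty vote table")
    ranking = rank_by_votes(table)
    nan = float("nan")
    rows: list[SweepRow] = []
    cache: dict[int, MetricsReport] = {}  # nested sweep => size identifies the subset
    for t0 in range(table.max_votes):
        n_sel = int(np.count_nonzero(ranking.votes > t0))
        subset = tuple(ranking.gene_ids[:n_sel])
        if n_sel == 0:
            rows.append(SweepRow(t0, subset, 0, nan, nan, nan))
            continue
        if n_sel not in cache:
            cache[n_sel] = evaluate_subset(
                data, subset, eval_classifier, k_eval, seed, eval_params
            )
        rep = cache[n_sel]
        rows.append(
            SweepRow(t0, subset, n_sel, rep.accuracy, rep.sensitivity, rep.specificity)
        )

    candidates = [r for r in rows if r.size > 0]
    if not candidates:
        raise DataValidationError("no gene ever received a vote; nothing to select")
    if max_genes is not None:
        capped = [r for r in candidates if r.size <= max_genes]
        if capped:
            candidates = capped
        else:
            logger.warning(
                "max_genes=%d excludes every nonempty candidate; cap ignored", max_genes
            )
    best = candidates[0]
    for row in candidates[1:]:
        if row.accuracy >= best.accuracy:  # later rows have larger t0
            best = row
    return SweepResult(
        rows=rows,
        chosen_t0=best.t0,
        final_subset=best.gene_ids,
        eval_classifier=eval_classifier,
    )


class WERFE:
    """Ensemble wrapper gene-selection model.

    Parameters
    ----------
    data : ExpressionDataset
        Samples x genes expression with binary labels.
    selectors : list of Selector, optional
        Base RFE selectors; defaults to SVM-RFE + RF-RFE.
    k : int
        Fold count of the selection cross-validation (default 10).
    eval_classifier, eval_params
        Classifier scoring each threshold candidate (default linear SVM).
    k_eval : int
        Fold count of the candidate-evaluation CV (default 10).
    max_genes : int, optional
        Cap on the final subset size when trading size against accuracy.

    Examples
    --------
    >>> from werfe import WERFE, synthetic
    >>> data, truth = synthetic.generate(synthetic.preset("nki70-like", seed=7))
    >>> results = WERFE(data).fit(seed=7)     # doctest: +SKIP
    >>> print(results.summary())              # doctest: +SKIP
    """

    def __init__(
        self,
        data: ExpressionDataset,
        selectors: list[Selector] | None = None,
        k: int = 10,
        eval_classifier: str = "svm",
        eval_params: dict | None = None,
        k_eval: int = 10,
        max_genes: int | None = None,
    ) -> None:
        self.data = data
        self.selectors = selectors if selectors is not None else default_selectors()
        if not self.selectors:
            raise ConfigError("selector list must not be empty")
        self.k = k
        self.eval_classifier = eval_classifier
        self.eval_params = eval_params or {}
        self.k_eval = k_eval
        self.max_genes = max_genes

    @classmethod
    def from_files(
        cls,
        matrix_path,
        labels_path=None,
        orientation: str = "samples_as_rows",
        delimiter: str = ",",
        label_column: str | None = None,
        **kwargs,
    ) -> "WERFE":
        """Build the model straight from delimited matrix/label files."""
        from .io import read_expression_matrix

        data = read_expression_matrix(
            matrix_path,
            orientation=orientation,
            delimiter=delimiter,
            labels_path=labels_path,
            label_column=label_column,
        )
        return cls(data, **kwargs)

    def fit(self, seed: int) -> "WERFEResults":
        """Run selection, ranking, the threshold sweep and final scoring."""
        vote_table, fold_subsets = ensemble_vote(
            self.data, self.selectors, k=self.k, seed=seed, return_fold_subsets=True
        )
        ranking = rank_by_votes(vote_table)
        sweep = threshold_sweep(
            self.data,
            vote_table,
            eval_classifier=self.eval_classifier,
            k_eval=self.k_eval,
            seed=seed,
            eval_params=self.eval_params,
            max_genes=self.max_genes,
        )
        final_metrics = evaluate_subset(
            self.data,
            sweep.final_subset,
            self.eval_classifier,
            self.k_eval,
            seed,
            self.eval_params,
            with_roc=True,
        )
        return WERFEResults(
            model=self,
            seed=seed,
            vote_table=vote_table,
            ranking=ranking,
            sweep=sweep,
            metrics=final_metrics,
            fold_subsets=fold_subsets,
        )


@dataclass
class WERFEResults:
    """Fitted WERFE output: votes, ranking, sweep and final-subset metrics."""

    model: WERFE
    seed: int
    vote_table: VoteTable
    ranking: RankedGeneList
    sweep: SweepResult
    metrics: MetricsReport
    fold_subsets: list[tuple[int, str, tuple[str, ...]]]

    @property
    def final_subset(self) -> tuple[str, ...]:
        return self.sweep.final_subset

    @property
    def chosen_t0(self) -> int:
        return self.sweep.chosen_t0

    def summary(self) -> str:
        """Human-readable account of the fitted selection."""
        m = self.model
        head = [
            "WERFE gene selection results",
            "=" * 60,
            f"Samples: {m.data.n_samples}   Genes: {m.data.n_genes}   "
            f"Folds: {m.k}   Selectors: {len(m.selectors)} "
            f"({', '.join(s.name for s in m.selectors)})",
            f"Evaluation: {m.eval_classifier} classifier, "
            f"{m.k_eval}-fold CV, seed {self.seed}",
            "",
            f"Vote range observed: {int(self.vote_table.votes.min())}"
            f"-{int(self.vote_table.votes.max())} of possible "
            f"0-{self.vote_table.max_votes}",
            f"Chosen threshold t0: {self.chosen_t0}",
            f"Final subset ({len(self.final_subset)} genes): "
            + ", ".join(self.final_subset[:10])
            + (" ..." if len(self.final_subset) > 10 else ""),
            "",
            self.metrics.summary(),
            "",
            "Threshold sweep (nonempty candidates):",
        ]
        tbl = self.sweep.to_frame()
        tbl = tbl[tbl["gene_number"] > 0]
        head.append(tbl.to_string(index=False, float_format=lambda x: f"{x:.2f}"))
        return "\n".join(head)

    def plot_roc(self, ax=None):
        """ROC curve of the final subset's pooled out-of-fold scores."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = self.metrics.roc_points
        ax.plot(pts[:, 0], pts[:, 1], label=f"AUC = {self.metrics.auc:.3f}")
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(loc="lower right")
        return ax

    def save(self, out_dir) -> None:
        """Write vote table, sweep table, final genes, metrics and ROC TSVs."""
        import json
        from pathlib import Path

        from .io import write_gene_subset

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.vote_table.to_frame().to_csv(out / "vote_table.tsv", sep="\t", index=False)
        self.sweep.to_frame().to_csv(out / "sweep.tsv", sep="\t", index=False)
        votes = dict(zip(self.ranking.gene_ids, self.ranking.votes.tolist()))
        write_gene_subset(
            list(self.final_subset),
            [votes[g] for g in self.final_subset],
            out / "final_genes.tsv",
        )
        payload = self.metrics.to_dict()
        payload.update(
            {
                "chosen_t0": self.chosen_t0,
                "final_subset_size": len(self.final_subset),
                "seed": self.seed,
            }
        )
        (out / "metrics.json").write_text(json.dumps(payload, indent=2) + "\n")
        if self.metrics.roc_points is not None:
            pd.DataFrame(
                {
                    "threshold": self.metrics.roc_thresholds,
                    "fpr": self.metrics.roc_points[:, 0],
                    "tpr": self.metrics.roc_points[:, 1],
                }
            ).to_csv(out / "roc.tsv", sep="\t", index=False)
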