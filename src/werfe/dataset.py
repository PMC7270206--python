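"""The expression-matrix container shared by every stage of the pipeline.

An :class:`ExpressionDataset` is an m × n real matrix of expression values
(samples in rows, genes in columns), a binary class label per sample, and
unique gene identifiers.  Every selector, ranker and evaluator in this
package consumes and produces views of this one type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataValidationError

__all__ = ["ExpressionDataset"]


@dataclass
class ExpressionDataset:
    """Samples × genes expression matrix with binary labels.

    Parameters
    ----------
    matrix : array-like of shape (m, n)
        Real-valued expression values; no missing entries allowed.
    labels : array-like of shape (m,)
        Binary class per sample, values in {0, 1}; both classes must be
        present (class 1 is the positive class throughout the package).
    gene_ids : sequence of str
        n unique gene identifiers, one per column.
    sample_ids : sequence of str, optional
        m sample identifiers; auto-generated (``S1`` ...) when absent.
    """

    matrix: np.ndarray
    labels: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise DataValidationError(
                f"expression matrix must be 2-dimensional, got ndim={self.matrix.ndim}"
            )
        m, n = self.matrix.shape
        if not np.isfinite(self.matrix).all():
            bad = np.argwhere(~np.isfinite(self.matrix))[0]
            raise DataValidationError(
                f"matrix contains a non-finite value at sample index {bad[0]}, "
                f"gene index {bad[1]} (missing values must be rejected or imputed on load)"
            )

        labels = np.asarray(self.labels)
        if labels.shape != (m,):
            raise DataValidationError(
                f"label count {labels.shape} does not match sample count {m}"
            )
        uniq = set(np.unique(labels).tolist())
        if not uniq <= {0, 1, 0.0, 1.0}:
            raise DataValidationError(
                f"labels must take values in {{0, 1}}; found {sorted(uniq)}"
            )
        self.labels = labels.astype(int)
        if len(set(self.labels.tolist())) < 2:
            raise DataValidationError(
                "both classes must be present; got a single-class label vector"
            )

        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.gene_ids) != n:
            raise DataValidationError(
                f"{len(self.gene_ids)} gene identifiers for {n} matrix columns"
            )
        if len(set(self.gene_ids)) != n:
            seen: set[str] = set()
            dup = next(g for g in self.gene_ids if g in seen or seen.add(g))
            raise DataValidationError(f"duplicate gene identifier: {dup!r}")

        if self.sample_ids is None:
            self.sample_ids = [f"S{i + 1}" for i in range(m)]
        else:
            self.sample_ids = [str(s) for s in self.sample_ids]
            if len(self.sample_ids) != m:
                raise DataValidationError(
                    f"{len(self.sample_ids)} sample identifiers for {m} matrix rows"
                )

    # -- shape accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """(count of class 0, count of class 1)."""
        return int((self.labels == 0).sum()), int((self.labels == 1).sum())

    # -- views -------------------------------------------------------------

    def gene_index(self, gene_ids) -> np.ndarray:
        """Column indices for the given gene identifiers (order preserved)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as exc:
            raise DataValidationError(f"unknown gene identifier: {exc.args[0]!r}") from None

    def subset_genes(self, gene_ids) -> "ExpressionDataset":
        """Restrict to the named genes, in the order given."""
        idx = self.gene_index(gene_ids)
        return ExpressionDataset(
            matrix=self.matrix[:, idx],
            labels=self.labels.copy(),
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
        )

    def take_samples(self, indices) -> "ExpressionDataset":
        """Restrict to the given sample rows (for fold splits)."""
        indices = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            matrix=self.matrix[indices],
            labels=self.labels[indices],
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in indices],
        )
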