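"""Reading and writing expression matrices, labels and gene lists.

All formats are plain delimited text.  Matrices may be stored with samples
in rows (canonical) or genes in rows; either orientation loads to the same
canonical samples × genes dataset.  Labels can live in a named column of
the matrix file or in a separate single-column file.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .errors import DataValidationError

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
    "write_gene_subset",
    "read_gene_subset",
]


def _to_numeric(df: pd.DataFrame) -> pd.DataFrame:
    """Convert all cells to float, naming the first offending cell on failure.

    Empty cells become NaN (handled by the caller as missing values); any
    non-numeric text raises a parse error locating the cell.
    """
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = df.index[np.flatnonzero(bad.to_numpy())[0]]
            raise DataValidationError(
                f"malformed numeric cell at row {row!r}, column {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        out[col] = converted
    return pd.DataFrame(out, index=df.index)


def read_expression_matrix(
    path,
    orientation: str = "samples_as_rows",
    delimiter: str = ",",
    *,
    label_column: str | None = None,
    labels_path=None,
    labels=None,
    impute_missing: bool = False,
) -> ExpressionDataset:
    """Load a delimited expression matrix into canonical orientation.

    Parameters
    ----------
    path
        Delimited text file; first column holds row identifiers, first row
        column identifiers.
    orientation : {"samples_as_rows", "genes_as_rows"}
        Layout of the file; ``genes_as_rows`` files are transposed on load.
    delimiter
        Field separator.
    label_column
        Name of a column of `path` (after orientation is resolved) holding
        the 0/1 labels; it is removed from the matrix.
    labels_path
        Separate single-column label file (alternative to `label_column`).
    labels
        In-memory label vector (alternative to both file options).
    impute_missing
        When True, missing cells are filled with the per-gene mean;
        otherwise any missing cell is an error.
    """
    if orientation not in ("samples_as_rows", "genes_as_rows"):
        raise DataValidationError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=delimiter, index_col=0, float_precision="round_trip")
    df = _to_numeric(df)
    if orientation == "genes_as_rows":
        df = df.T

    if label_column is not None:
        if label_column not in df.columns:
            raise DataValidationError(f"label column {label_column!r} not found")
        labels = df[label_column].to_numpy()
        df = df.drop(columns=[label_column])
    elif labels_path is not None:
        labels = read_labels(labels_path)
    elif labels is None:
        raise DataValidationError(
            "no labels supplied: pass label_column, labels_path or labels"
        )

    matrix = df.to_numpy(dtype=float)
    if np.isnan(matrix).any():
        if impute_missing:
            col_means = np.nanmean(matrix, axis=0)
            nan_r, nan_c = np.where(np.isnan(matrix))
            matrix[nan_r, nan_c] = col_means[nan_c]
        else:
            r, c = np.argwhere(np.isnan(matrix))[0]
            raise DataValidationError(
                f"missing value at sample {df.index[r]!r}, gene {df.columns[c]!r}; "
                "pass impute_missing=True to fill with per-gene means"
            )

    return ExpressionDataset(
        matrix=matrix,
        labels=np.asarray(labels),
        gene_ids=[str(c) for c in df.columns],
        sample_ids=[str(i) for i in df.index],
    )


def write_expression_matrix(
    dataset: ExpressionDataset,
    path,
    orientation: str = "samples_as_rows",
    delimiter: str = ",",
) -> None:
    """Write a dataset as delimited text at full repr precision."""
    df = pd.DataFrame(
        dataset.matrix, index=dataset.sample_ids, columns=dataset.gene_ids
    )
    if orientation == "genes_as_rows":
        df = df.T
    elif orientation != "samples_as_rows":
        raise DataValidationError(f"unknown orientation {orientation!r}")
    # repr-level precision so write->read round-trips bit-exactly
    df.to_csv(path, sep=delimiter, float_format=lambda x: repr(float(x)))


def read_labels(path) -> np.ndarray:
    """Read a single-column label file; a non-numeric first line is a header."""
    with open(path) as fh:
        tokens = [line.strip() for line in fh if line.strip() != ""]
    if not tokens:
        raise DataValidationError(f"empty label file: {path}")
    try:
        float(tokens[0])
    except ValueError:
        tokens = tokens[1:]
    try:
        values = np.array([float(t) for t in tokens])
    except ValueError as exc:
        raise DataValidationError(f"malformed label value in {path}: {exc}") from None
    return values


def write_labels(labels, path, header: str = "label") -> None:
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for v in np.asarray(labels).astype(int):
            fh.write(f"{v}\n")


def write_gene_subset(gene_ids, votes, path) -> None:
    """Write a two-column (gene_id, votes) TSV in the order given."""
    gene_ids = list(gene_ids)
    votes = list(votes)
    if len(gene_ids) != len(votes):
        raise DataValidationError(
            f"{len(gene_ids)} gene identifiers but {len(votes)} vote counts"
        )
    with open(path, "w") as fh:
        fh.write("gene_id\tvotes\n")
        for g, v in zip(gene_ids, votes):
            fh.write(f"{g}\t{v}\n")


def read_gene_subset(path) -> tuple[list[str], list[int]]:
    """Read a two-column gene/votes TSV written by :func:`write_gene_subset`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise DataValidationError(f"{path} has no 'gene_id' column")
    votes = df["votes"].astype(int).tolist() if "votes" in df.columns else [0] * len(df)
    return df["gene_id"].tolist(), votes
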