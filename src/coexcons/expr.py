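"""Expression-matrix loading, validation, filtering and transformation.

Every correlation downstream operates on a gene x sample abundance table.
Genes are filtered on the raw FPKM scale (mean and coefficient of variation)
and then log2-transformed; the container tracks which scale it is on so a
matrix cannot be filtered or transformed twice by accident.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ExpressionError",
    "read_expression_matrix",
    "write_expression_matrix",
    "filter_expression",
    "log_transform",
    "average_replicates",
]


class ExpressionError(ValueError):
    """Structured validation error for expression matrices."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """A gene x sample abundance table.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample. All entries
        must be finite, and non-negative while on the FPKM scale.
    scale_tag
        ``"fpkm"`` for raw abundances, ``"log2"`` after log transformation.
    """

    values: pd.DataFrame
    scale_tag: str = "fpkm"

    def __post_init__(self) -> None:
        if self.scale_tag not in ("fpkm", "log2"):
            raise ExpressionError(f"unknown scale_tag {self.scale_tag!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ExpressionError(f"duplicate gene ids: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise ExpressionError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ExpressionError("non-numeric values in expression matrix")
        if arr.size and not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ExpressionError(
                f"non-finite value at gene {idx[i]!r}, sample {cols[j]!r}"
            )
        if self.scale_tag == "fpkm" and arr.size and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ExpressionError(
                f"negative FPKM at gene {idx[i]!r}, sample {cols[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def require_samples(self, n: int) -> None:
        if self.shape[1] < n:
            raise ExpressionError(
                f"need at least {n} samples, matrix has {self.shape[1]}"
            )


def read_expression_matrix(path, sep: str = "\t") -> ExpressionMatrix:
    """Read a TSV expression matrix (header = samples, first column = gene ids).

    Lines starting with ``#`` are treated as comments. Raises
    :class:`ExpressionError` on duplicate ids, non-numeric cells or an empty
    file, naming the offending gene/sample.
    """
    try:
        raw = pd.read_csv(path, sep=sep, index_col=0, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise ExpressionError(f"{path}: no data rows") from None
    if raw.shape[0] == 0:
        raise ExpressionError(f"{path}: no data rows")
    values = pd.DataFrame(index=raw.index.astype(str), dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad.to_numpy().argmax()]
            raise ExpressionError(
                f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}: "
                f"{raw.loc[gene, col]!r}"
            )
        if converted.isna().any():
            gene = raw.index[converted.isna().to_numpy().argmax()]
            raise ExpressionError(
                f"{path}: missing value at gene {gene!r}, sample {col!r}"
            )
        values[str(col)] = converted.to_numpy(dtype=float)
    return ExpressionMatrix(values=values, scale_tag="fpkm")


def write_expression_matrix(m: ExpressionMatrix, path, header_comment: str | None = None) -> None:
    """Write a matrix as TSV with 6 significant digits, optional # header."""
    buf = io.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    out = m.values.copy()
    out.index.name = "gene_id"
    out.to_csv(buf, sep="\t", float_format="%.6g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def filter_expression(
    m: ExpressionMatrix,
    min_mean: float = 0.1,
    min_cv: float = 0.5,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Remove non-expressed and constitutively expressed genes.

    A gene is removed when its mean FPKM is below ``min_mean`` (reason
    ``low_mean``) or its coefficient of variation sd/mean (sample sd, n-1
    denominator, on the raw FPKM row) is below ``min_cv`` (reason ``low_cv``).
    Both thresholds are strict: boundary values are retained. Returns the
    filtered matrix and a removal report with columns
    ``gene_id, mean_fpkm, cv, reasons``.
    """
    if m.scale_tag != "fpkm":
        raise ExpressionError("filter_expression requires an FPKM-scale matrix")
    if m.shape[1] < 2:
        raise ExpressionError("CV undefined with fewer than 2 samples")
    arr = m.values.to_numpy(dtype=float)
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)
    low_mean = mean < min_mean
    low_cv = cv < min_cv
    removed = low_mean | low_cv
    reasons = []
    for lm, lc in zip(low_mean, low_cv):
        tags = (["low_mean"] if lm else []) + (["low_cv"] if lc else [])
        reasons.append(";".join(tags))
    report = pd.DataFrame(
        {
            "gene_id": m.values.index[removed],
            "mean_fpkm": mean[removed],
            "cv": cv[removed],
            "reasons": [r for r, rm in zip(reasons, removed) if rm],
        }
    ).reset_index(drop=True)
    kept = ExpressionMatrix(values=m.values.loc[~removed], scale_tag="fpkm")
    return kept, report


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Apply x -> log2(x + 1) cell-wise; guards against double transformation.

    The pseudocount keeps zero-FPKM cells finite (0 -> 0) and the map strictly
    monotone, so rank-based statistics are unchanged by it.
    """
    if m.scale_tag == "log2":
        raise ExpressionError("matrix is already log2-transformed")
    return ExpressionMatrix(values=np.log2(m.values + 1.0), scale_tag="log2")


def average_replicates(m: ExpressionMatrix, groups: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse replicate columns to one column per group (arithmetic mean).

    ``groups`` maps every sample id to a group (tissue) label; group column
    order follows first appearance in the sample order.
    """
    missing = [s for s in m.sample_ids if s not in groups]
    if missing:
        raise ExpressionError(f"samples not assigned to any group: {missing}")
    order: list[str] = []
    for s in m.sample_ids:
        g = groups[s]
        if g not in order:
            order.append(g)
    cols = {}
    for g in order:
        members = [s for s in m.sample_ids if groups[s] == g]
        cols[g] = m.values[members].mean(axis=1)
    return ExpressionMatrix(values=pd.DataFrame(cols, index=m.values.index), scale_tag=m.scale_tag)
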