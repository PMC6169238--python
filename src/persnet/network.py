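"""Weighted gene coexpression network construction.

An expression matrix becomes a weighted network in three steps: keep the
genes with the largest spread (variance or IQR), take the absolute Pearson
correlation between gene profiles as the similarity (so strongly
anticorrelated genes are as similar as correlated ones), and map similarity
s to dissimilarity 1 - s, placing maximal coexpression at distance 0.  The
dissimilarity matrix is the input to the Rips filtration; no edge threshold
is ever chosen — persistence examines all thresholds at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "SimilarityMatrix",
    "DissimilarityMatrix",
    "filter_genes",
    "correlation_similarity",
    "similarity_to_dissimilarity",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples numeric table with row and column labels."""

    gene_ids: Sequence[str]
    sample_ids: Sequence[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {v.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.any(~np.isfinite(v)):
            raise ValueError("expression matrix contains missing/non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric gene-gene similarity in [0, 1] with unit diagonal."""

    labels: Sequence[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("similarity matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("similarity entries must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("similarity diagonal must be 1")


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric gene-gene dissimilarity in [0, 1] with zero diagonal."""

    labels: Sequence[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("dissimilarity matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(v < 0) or np.any(v > 1 + 1e-12):
            raise ValueError("dissimilarity entries must lie in [0, 1]")
        if np.any(np.diag(v) != 0):
            raise ValueError("dissimilarity diagonal must be 0")

    @property
    def n(self) -> int:
        return len(self.labels)


def _spread(values: np.ndarray, statistic: str) -> np.ndarray:
    if statistic == "variance":
        return values.var(axis=1, ddof=1)
    if statistic == "iqr":
        q75, q25 = np.percentile(values, [75, 25], axis=1)
        return q75 - q25
    raise ValueError(f"unknown spread statistic {statistic!r}")


def filter_genes(
    expr: ExpressionMatrix, keep: int = 400, statistic: str = "variance"
) -> ExpressionMatrix:
    """Keep the ``keep`` genes with the largest spread.

    Genes with zero spread are excluded before ranking (a constant profile
    has no defined correlation); the original row order is preserved among
    the survivors.  Raises if fewer than ``keep`` genes have nonzero spread.
    """
    if keep < 1:
        raise ValueError("keep must be a positive integer")
    spread = _spread(expr.values, statistic)
    eligible = np.flatnonzero(spread > 0)
    if keep > len(eligible):
        raise ValueError(
            f"requested {keep} genes but only {len(eligible)} have nonzero "
            f"{statistic} (of {expr.n_genes} total)"
        )
    top = eligible[np.argsort(spread[eligible], kind="stable")[::-1][:keep]]
    top.sort()  # preserve original row order among survivors
    return ExpressionMatrix(
        [expr.gene_ids[i] for i in top], list(expr.sample_ids), expr.values[top]
    )


def correlation_similarity(expr: ExpressionMatrix) -> SimilarityMatrix:
    """Absolute Pearson correlation between gene profiles.

    Entry (i, j) is |r| of rows i and j; the diagonal is exactly 1.  Requires
    at least 3 samples and no constant rows (filter first).
    """
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples for a meaningful correlation")
    if np.any(expr.values.var(axis=1) == 0):
        raise ValueError(
            "constant gene rows have undefined correlation; run filter_genes first"
        )
    r = np.corrcoef(expr.values)
    s = np.clip(np.abs(r), 0.0, 1.0)
    np.fill_diagonal(s, 1.0)
    s = (s + s.T) / 2.0
    return SimilarityMatrix(list(expr.gene_ids), s)


def similarity_to_dissimilarity(sim: SimilarityMatrix) -> DissimilarityMatrix:
    """Map similarity s to dissimilarity d = 1 - s (zero diagonal)."""
    d = 1.0 - sim.values
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return DissimilarityMatrix(list(sim.labels), d)


def expression_to_dissimilarity(
    expr: ExpressionMatrix, keep: "int | None" = None, statistic: str = "variance"
) -> DissimilarityMatrix:
    """Full network-construction chain: filter -> |r| similarity -> 1 - s."""
    if keep is not None:
        expr = filter_genes(expr, keep=keep, statistic=statistic)
    return similarity_to_dissimilarity(correlation_similarity(expr))
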