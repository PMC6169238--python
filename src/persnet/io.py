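"""Readers and writers for the plain-text formats used throughout.

Expression matrices are delimited text (first column gene IDs, header row
sample IDs; delimiter auto-detected).  Similarity/dissimilarity and network
distance matrices are labeled TSV.  Persistence diagrams are TSV with
columns (dimension, birth, death, essential), essential deaths written as
the literal string "inf"; rows are in deterministic (dimension, birth,
death) order.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .distances import NetworkDistanceMatrix
from .homology import PersistenceDiagram, PersistencePair
from .network import DissimilarityMatrix, ExpressionMatrix, SimilarityMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "write_labeled_matrix",
    "read_dissimilarity",
    "read_distance_matrix",
    "write_diagram",
    "read_diagram",
]


def read_expression(path: "str | Path") -> ExpressionMatrix:
    """Read a genes x samples table; rows with missing values are dropped."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    n_before = len(df)
    df = df.dropna(axis=0, how="any")
    dropped = n_before - len(df)
    if dropped:
        import logging

        logging.getLogger(__name__).warning(
            "%s: dropped %d gene rows with missing values", path, dropped
        )
    return ExpressionMatrix(
        [str(g) for g in df.index],
        [str(s) for s in df.columns],
        df.to_numpy(dtype=float),
    )


def write_expression(expr: ExpressionMatrix, path: "str | Path") -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_labeled_matrix(
    labels: Sequence[str], values: np.ndarray, path: "str | Path"
) -> None:
    """Symmetric labeled matrix as TSV, 12 significant digits."""
    df = pd.DataFrame(values, index=list(labels), columns=list(labels))
    df.index.name = "id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def _read_labeled_matrix(path: "str | Path") -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(c) for c in df.columns], df.to_numpy(dtype=float)


def read_dissimilarity(path: "str | Path") -> DissimilarityMatrix:
    labels, values = _read_labeled_matrix(path)
    values = (values + values.T) / 2.0  # undo round-trip rounding asymmetry
    np.fill_diagonal(values, 0.0)
    return DissimilarityMatrix(labels, values)


def read_distance_matrix(path: "str | Path") -> NetworkDistanceMatrix:
    labels, values = _read_labeled_matrix(path)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return NetworkDistanceMatrix(tuple(labels), values)


def write_diagram(diagram: PersistenceDiagram, path: "str | Path") -> None:
    with open(path, "w") as fh:
        fh.write("dimension\tbirth\tdeath\tessential\n")
        for p in diagram.pairs:
            death = "inf" if p.essential else f"{p.death:.12g}"
            fh.write(f"{p.dimension}\t{p.birth:.12g}\t{death}\t{int(p.essential)}\n")


def read_diagram(path: "str | Path") -> PersistenceDiagram:
    df = pd.read_csv(path, sep="\t")
    pairs = [
        PersistencePair(
            int(row.dimension),
            float(row.birth),
            math.inf if str(row.death) == "inf" else float(row.death),
        )
        for row in df.itertuples()
    ]
    return PersistenceDiagram.from_pairs(pairs)
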