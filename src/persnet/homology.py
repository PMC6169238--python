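"""Persistent homology of a Rips filtration over GF(2).

Two computation paths are provided.  :func:`reduce_boundary_matrix` is the
standard left-to-right column reduction of the GF(2) boundary matrix with
lowest-one pairing, returning 0- and 1-dimensional birth/death pairs.
:func:`h0_via_mst` exploits the fact that, for a clique filtration with all
vertices born at 0, the deaths of connected components are exactly the
minimum-spanning-tree merge values (Kruskal order), which is far cheaper and
serves as the default path when loops are not needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .filtration import Filtration, build_rips_filtration

__all__ = [
    "PersistencePair",
    "PersistenceDiagram",
    "reduce_boundary_matrix",
    "h0_via_mst",
    "betti_at",
    "rips_persistence",
]


@dataclass(frozen=True)
class PersistencePair:
    """A single (birth, death) feature of fixed homology dimension.

    ``death`` is ``math.inf`` for essential classes — features that never die
    within the filtration, such as the one connected component surviving to
    the maximum threshold.
    """

    dimension: int
    birth: float
    death: float

    @property
    def essential(self) -> bool:
        return math.isinf(self.death)

    @property
    def persistence(self) -> float:
        return self.death - self.birth


@dataclass(frozen=True)
class PersistenceDiagram:
    """Multiset of persistence pairs, sorted by (dimension, birth, death)."""

    pairs: tuple[PersistencePair, ...]

    @staticmethod
    def from_pairs(pairs: Iterable[PersistencePair]) -> "PersistenceDiagram":
        return PersistenceDiagram(
            tuple(sorted(pairs, key=lambda p: (p.dimension, p.birth, p.death)))
        )

    def in_dimension(self, dimension: int) -> tuple[PersistencePair, ...]:
        return tuple(p for p in self.pairs if p.dimension == dimension)

    def points(self, dimension: int, include_essential: bool = False) -> np.ndarray:
        """Finite (birth, death) points of one dimension as an (m, 2) array."""
        pts = [
            (p.birth, p.death)
            for p in self.pairs
            if p.dimension == dimension and (include_essential or not p.essential)
        ]
        return np.asarray(pts, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.pairs)


def reduce_boundary_matrix(filt: Filtration) -> PersistenceDiagram:
    """Compute persistence pairs by GF(2) boundary-matrix reduction.

    Columns (one per simplex, in filtration order) are reduced left to right:
    while a column shares its lowest nonzero row with an earlier reduced
    column, that column is added to it over GF(2).  A column that reduces to
    zero creates a class; a nonzero column kills the class created at its
    lowest-one row.  Dimensions are processed from high to low with the
    clearing (twist) optimization: a simplex known to be a death can have its
    column zeroed without reduction.

    Pairs with equal birth and death are discarded; unpaired 0- and
    1-simplices become essential pairs.  Homology of dimension 2 is never
    reported (triangles exist only to kill loops).
    """
    filt.validate()
    n = len(filt.simplices)
    dims = np.fromiter((s.dimension for s in filt.simplices), dtype=np.int8, count=n)
    vals = np.fromiter((s.value for s in filt.simplices), dtype=float, count=n)

    # Column j as a Python-int bitmask over face indices; bit i set <=> row i.
    columns: list[int] = [0] * n
    for j, s in enumerate(filt.simplices):
        mask = 0
        for face in s.faces():
            mask |= 1 << filt.index_of(face)
        columns[j] = mask

    pivot_of_row: dict[int, int] = {}  # lowest-one row -> column index
    cleared = [False] * n
    pairs: list[PersistencePair] = []
    paired = [False] * n

    for dim in range(max(dims, default=0), 0, -1):
        for j in range(n):
            if dims[j] != dim or cleared[j]:
                continue
            col = columns[j]
            while col:
                low = col.bit_length() - 1
                other = pivot_of_row.get(low)
                if other is None:
                    break
                col ^= columns[other]
            columns[j] = col
            if col:
                low = col.bit_length() - 1
                pivot_of_row[low] = j
                paired[low] = paired[j] = True
                cleared[low] = True  # twist: the birth simplex's own column dies
                if vals[low] < vals[j]:
                    pairs.append(
                        PersistencePair(int(dims[low]), float(vals[low]), float(vals[j]))
                    )

    for j in range(n):
        if not paired[j] and dims[j] <= 1:
            pairs.append(PersistencePair(int(dims[j]), float(vals[j]), math.inf))
    return PersistenceDiagram.from_pairs(pairs)


def _kruskal_merge_weights(values: np.ndarray) -> np.ndarray:
    """Weights at which Kruskal's algorithm merges components (sorted)."""
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = values[iu, ju]
    order = np.argsort(w, kind="stable")
    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merges: list[float] = []
    for e in order:
        a, b = find(int(iu[e])), find(int(ju[e]))
        if a != b:
            parent[a] = b
            merges.append(float(w[e]))
            if len(merges) == n - 1:
                break
    return np.asarray(merges)


def h0_via_mst(D: "np.ndarray | object") -> PersistenceDiagram:
    """Dimension-0 persistence directly from the minimum spanning tree.

    Every vertex is born at threshold 0; as the threshold grows, components
    only merge and none is born, so the finite deaths are exactly the n-1 MST
    edge weights.  Returns the dimension-0 diagram only: n-1 finite pairs
    (0, w) — those with w = 0 discarded as zero-persistence — plus the single
    essential component.
    """
    values = np.asarray(getattr(D, "values", D), dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.any(values < 0):
        raise ValueError("dissimilarity matrix must be nonnegative")
    pairs = [
        PersistencePair(0, 0.0, w) for w in _kruskal_merge_weights(values) if w > 0.0
    ]
    pairs.append(PersistencePair(0, 0.0, math.inf))
    return PersistenceDiagram.from_pairs(pairs)


def betti_at(diagram: PersistenceDiagram, threshold: float) -> tuple[int, int]:
    """Betti numbers (beta0, beta1) at a threshold.

    A pair is alive at ``t`` when birth <= t < death, with essential pairs
    counting as death = infinity.  Yields the component and loop counts of the
    Rips complex at that scale.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    b = [0, 0]
    for p in diagram.pairs:
        if p.dimension <= 1 and p.birth <= threshold < p.death:
            b[p.dimension] += 1
    return b[0], b[1]


def rips_persistence(
    D: "np.ndarray | object",
    max_dim: int = 2,
    max_value: float = 1.0,
    h0_fast: bool = True,
) -> PersistenceDiagram:
    """Convenience wrapper: 0- and 1-dimensional diagram of a network.

    With ``max_dim=1`` (components only) the MST shortcut is used when
    ``h0_fast`` is set.  With ``max_dim=2`` the full reduction runs, capped at
    ``max_value`` (the natural maximum of a 1 - |r| network is 1.0).
    """
    if max_dim == 1 and h0_fast:
        return h0_via_mst(D)
    filt = build_rips_filtration(D, max_dim=max_dim, max_value=max_value)
    return reduce_boundary_matrix(filt)
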