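"""Vietoris-Rips clique filtration of a weighted network.

The Rips complex at scale ``eps`` of a dissimilarity matrix D contains a
k-simplex for every (k+1)-tuple of vertices that are pairwise within
dissimilarity ``eps``.  Because the complex is a clique (flag) complex, the
edges determine everything: the filtration value of a higher simplex is the
maximum of its edge values.  Increasing ``eps`` yields the nested family of
complexes whose persistent homology is computed downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator

import numpy as np

__all__ = ["Simplex", "Filtration", "build_rips_filtration"]


@dataclass(frozen=True, order=False)
class Simplex:
    """A simplex of the filtration: sorted vertex tuple plus filtration value."""

    vertices: tuple[int, ...]
    value: float

    def __post_init__(self) -> None:
        if any(a >= b for a, b in zip(self.vertices, self.vertices[1:])):
            raise ValueError(f"vertices must be strictly increasing: {self.vertices}")

    @property
    def dimension(self) -> int:
        return len(self.vertices) - 1

    def faces(self) -> Iterator[tuple[int, ...]]:
        """Codimension-1 faces (empty for vertices)."""
        if len(self.vertices) > 1:
            for i in range(len(self.vertices)):
                yield self.vertices[:i] + self.vertices[i + 1 :]

    def sort_key(self) -> tuple[float, int, tuple[int, ...]]:
        return (self.value, self.dimension, self.vertices)


@dataclass
class Filtration:
    """Ordered list of simplices with nondecreasing filtration values.

    The order is (value, dimension, lexicographic vertex tuple), which
    guarantees every face precedes its cofaces and makes the boundary-matrix
    reduction deterministic.
    """

    simplices: list[Simplex]
    n_vertices: int
    max_dim: int = 2
    _index: dict[tuple[int, ...], int] = field(default=None, repr=False)  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.simplices)

    def index_of(self, vertices: tuple[int, ...]) -> int:
        if self._index is None:
            self._index = {s.vertices: i for i, s in enumerate(self.simplices)}
        return self._index[vertices]

    def validate(self) -> None:
        """Check value monotonicity and the face-ordering invariant."""
        seen: dict[tuple[int, ...], int] = {}
        prev = -math.inf
        for pos, s in enumerate(self.simplices):
            if s.value < prev:
                raise ValueError(
                    f"filtration values decrease at position {pos} "
                    f"({s.value} < {prev})"
                )
            prev = s.value
            for face in s.faces():
                if face not in seen:
                    raise ValueError(
                        f"face {face} of simplex {s.vertices} missing or out of order"
                    )
            if s.dimension == 0 and s.value != 0.0:
                raise ValueError("vertex simplices must enter at value 0")
            seen[s.vertices] = pos


def build_rips_filtration(
    D: "np.ndarray | object",
    max_dim: int = 2,
    max_value: float = math.inf,
) -> Filtration:
    """Build the Rips clique filtration of a dissimilarity matrix.

    Parameters
    ----------
    D
        Symmetric nonnegative matrix with zero diagonal (a
        :class:`~persnet.network.DissimilarityMatrix` or a plain array).
    max_dim
        Highest simplex dimension to enumerate (1 or 2).  Triangles are needed
        to kill loops, so 1-dimensional homology requires ``max_dim=2``.
    max_value
        Simplices entering above this value are omitted, truncating the
        filtration.  The number of triangles grows cubically with the vertex
        count, so a cap keeps large networks tractable.

    Returns
    -------
    Filtration
        Vertices at value 0, edge {i,j} at D[i,j], triangle {i,j,k} at the
        maximum of its three edge values; ordered by
        (value, dimension, vertex tuple).
    """
    values = np.asarray(getattr(D, "values", D), dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.any(values < 0):
        raise ValueError("dissimilarity matrix must be nonnegative")
    if max_dim not in (1, 2):
        raise ValueError("max_dim must be 1 or 2")

    n = values.shape[0]
    simplices: list[Simplex] = [Simplex((i,), 0.0) for i in range(n)]
    for i, j in combinations(range(n), 2):
        v = values[i, j]
        if v <= max_value:
            simplices.append(Simplex((i, j), float(v)))
    if max_dim == 2:
        for i, j, k in combinations(range(n), 3):
            v = max(values[i, j], values[i, k], values[j, k])
            if v <= max_value:
                simplices.append(Simplex((i, j, k), float(v)))
    simplices.sort(key=Simplex.sort_key)
    return Filtration(simplices=simplices, n_vertices=n, max_dim=max_dim)
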