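"""Distances between persistence diagrams and the network distance matrix.

The bottleneck distance is the minimax matching cost between two diagrams
under the L-infinity plane metric: points may be matched to each other or to
their orthogonal projections on the diagonal (cost (death - birth)/2), so
diagrams of different sizes are comparable.  It is computed exactly by binary
search over the finite set of candidate costs, with feasibility at each
candidate decided by maximum bipartite matching — no floating tolerances are
involved, and the returned value is always one of the candidates.

The q-Wasserstein distance replaces the max by a sum of q-th powers and is
solved exactly as a square assignment problem on the two point sets padded
with diagonal projections.  Bottleneck is its q -> infinity limit and is never
larger than any d_q.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .homology import PersistenceDiagram

__all__ = [
    "bottleneck_distance",
    "wasserstein_distance",
    "pairwise_distance_matrix",
    "NetworkDistanceMatrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkDistanceMatrix:
    """Symmetric matrix of pairwise diagram distances between networks."""

    network_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.network_ids), len(self.network_ids)):
            raise ValueError("distance matrix shape does not match id count")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0) or np.any(v < 0):
            raise ValueError("distances must be nonnegative with zero diagonal")


def _finite_points(diagram: PersistenceDiagram, dimension: int) -> np.ndarray:
    """Off-diagonal finite points of one homology dimension.

    Essential classes are excluded: every connected network carries exactly
    one essential component, so it adds a constant zero term to any matching
    (essential-to-essential at cost 0) and no discriminative information.
    """
    return diagram.points(dimension, include_essential=False)


def _linf_cross(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Pairwise L-infinity distances between two (m,2) point sets."""
    if len(P) == 0 or len(Q) == 0:
        return np.zeros((len(P), len(Q)))
    return np.abs(P[:, None, :] - Q[None, :, :]).max(axis=2)


def _diag_cost(P: np.ndarray) -> np.ndarray:
    """L-infinity distance of each point to its diagonal projection."""
    if len(P) == 0:
        return np.zeros(0)
    return (P[:, 1] - P[:, 0]) / 2.0


def _feasible(cross: np.ndarray, da: np.ndarray, db: np.ndarray, t: float) -> bool:
    """Is there an augmented perfect matching with all costs <= t?

    Bipartite graph: left = points of A plus |B| diagonal slots, right =
    points of B plus |A| diagonal slots.  A point connects to every diagonal
    slot of the other side iff its own diagonal cost is <= t; diagonal slots
    connect to each other freely.
    """
    a, b = len(da), len(db)
    size = a + b
    if size == 0:
        return True
    M = np.zeros((size, size), dtype=bool)
    M[:a, :b] = cross <= t
    M[:a, b:] = (da <= t)[:, None]
    M[a:, :b] = (db <= t)[None, :]
    M[a:, b:] = True
    match = maximum_bipartite_matching(csr_matrix(M), perm_type="column")
    return bool(np.all(match >= 0))


def bottleneck_distance(
    A: PersistenceDiagram, B: PersistenceDiagram, dimension: int = 0
) -> float:
    """Exact bottleneck distance between two diagrams in one dimension.

    The optimum is attained at one of finitely many candidate costs — the
    point-to-point L-infinity distances and the point-to-diagonal costs — so a
    binary search over the sorted candidates, with a bipartite-matching
    feasibility test at each, returns the exact infimum.
    """
    PA = _finite_points(A, dimension)
    PB = _finite_points(B, dimension)
    if len(PA) == 0 and len(PB) == 0:
        logger.debug("both diagrams empty in dimension %d; distance 0", dimension)
        return 0.0
    cross = _linf_cross(PA, PB)
    da, db = _diag_cost(PA), _diag_cost(PB)
    candidates = np.unique(np.concatenate([cross.ravel(), da, db, [0.0]]))
    lo, hi = 0, len(candidates) - 1
    if _feasible(cross, da, db, float(candidates[lo])):
        return float(candidates[lo])
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _feasible(cross, da, db, float(candidates[mid])):
            hi = mid
        else:
            lo = mid
    return float(candidates[hi])


def wasserstein_distance(
    A: PersistenceDiagram,
    B: PersistenceDiagram,
    dimension: int = 0,
    q: float = 1.0,
) -> float:
    """Exact q-Wasserstein distance with L-infinity ground metric.

    Solved as a square assignment problem of size |A|+|B|: each point may be
    assigned to a point of the other diagram (cost L-inf^q) or to a diagonal
    slot (cost half its persistence, to the q); diagonal-to-diagonal costs 0.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    PA = _finite_points(A, dimension)
    PB = _finite_points(B, dimension)
    a, b = len(PA), len(PB)
    if a == 0 and b == 0:
        return 0.0
    size = a + b
    C = np.zeros((size, size))
    C[:a, :b] = _linf_cross(PA, PB) ** q
    C[:a, b:] = (_diag_cost(PA) ** q)[:, None]
    C[a:, :b] = (_diag_cost(PB) ** q)[None, :]
    rows, cols = linear_sum_assignment(C)
    return float(C[rows, cols].sum() ** (1.0 / q))


def pairwise_distance_matrix(
    diagrams: Sequence[tuple[str, PersistenceDiagram]],
    dimension: int = 0,
    metric: str = "bottleneck",
    q: float = 1.0,
) -> NetworkDistanceMatrix:
    """Assemble the symmetric matrix of pairwise diagram distances."""
    if len(diagrams) < 2:
        raise ValueError("need at least 2 diagrams")
    ids = [i for i, _ in diagrams]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate network ids in diagram list")
    if metric not in ("bottleneck", "wasserstein"):
        raise ValueError(f"unknown metric {metric!r}")
    n = len(diagrams)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "bottleneck":
                d = bottleneck_distance(diagrams[i][1], diagrams[j][1], dimension)
            else:
                d = wasserstein_distance(diagrams[i][1], diagrams[j][1], dimension, q)
            M[i, j] = M[j, i] = d
        logger.info("distances from %s: %d entries done", ids[i], n - i - 1)
    return NetworkDistanceMatrix(tuple(ids), M)
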