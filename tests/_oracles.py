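"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: diagram distances are
enumerated over all augmented bijections, and random symmetric matrices are
generated here rather than through the package's simulator.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np


def random_dissimilarity(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric matrix in [0,1] with zero diagonal."""
    M = rng.random((n, n))
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 0.0)
    return M


def random_diagram_points(rng: np.random.Generator, max_points: int) -> np.ndarray:
    """Random finite (birth, death) points with birth < death."""
    m = int(rng.integers(0, max_points + 1))
    births = rng.random(m)
    deaths = births + rng.random(m) * (1.0 - births) * 0.9 + 1e-3
    return np.column_stack([births, deaths]) if m else np.zeros((0, 2))


def _matching_costs(PA: np.ndarray, PB: np.ndarray):
    """Yield, for every augmented bijection, the list of its L-inf costs.

    A matching pairs some subset of A's points injectively with B's points;
    every unmatched point goes to its diagonal projection at cost
    (death - birth) / 2.
    """
    a, b = len(PA), len(PB)
    diag_a = (PA[:, 1] - PA[:, 0]) / 2.0 if a else np.zeros(0)
    diag_b = (PB[:, 1] - PB[:, 0]) / 2.0 if b else np.zeros(0)
    for k in range(min(a, b) + 1):
        for sub_a in combinations(range(a), k):
            for sub_b in permutations(range(b), k):
                costs = [
                    float(np.max(np.abs(PA[i] - PB[j])))
                    for i, j in zip(sub_a, sub_b)
                ]
                costs += [float(diag_a[i]) for i in range(a) if i not in sub_a]
                costs += [float(diag_b[j]) for j in range(b) if j not in sub_b]
                yield costs


def brute_bottleneck(PA: np.ndarray, PB: np.ndarray) -> float:
    """Exact bottleneck distance by enumeration (small diagrams only)."""
    if len(PA) == 0 and len(PB) == 0:
        return 0.0
    return min(max(costs, default=0.0) for costs in _matching_costs(PA, PB))


def brute_wasserstein(PA: np.ndarray, PB: np.ndarray, q: float) -> float:
    """Exact q-Wasserstein distance by enumeration (small diagrams only)."""
    if len(PA) == 0 and len(PB) == 0:
        return 0.0
    best = min(sum(c**q for c in costs) for costs in _matching_costs(PA, PB))
    return float(best ** (1.0 / q))
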