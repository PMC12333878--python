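"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths they check: the filtration oracle
tracks connected components with a hand-rolled disjoint-set structure while
scanning thresholds in descending order, and the permutation oracle
enumerates group assignments with plain Python arithmetic.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


class DisjointSet:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[ri] = rj
        return True


def filtration_birth_death(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Component births and cycle deaths of a complete weighted graph by
    explicit descending-threshold filtration with union-find.

    Edges are added in decreasing weight order; an edge merging two
    components records a component birth at its weight, any other edge
    records a cycle death at its weight.
    """
    W = np.asarray(weights, dtype=float)
    m = W.shape[0]
    edges = [(W[i, j], i, j) for i in range(m) for j in range(i + 1, m)]
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))
    ds = DisjointSet(m)
    births, deaths = [], []
    for w, i, j in edges:
        if ds.union(i, j):
            births.append(w)
        else:
            deaths.append(w)
    return np.sort(np.array(births)), np.sort(np.array(deaths))


def exhaustive_permutation_p(x, y) -> tuple[float, float]:
    """Exact permutation p-value by enumerating all C(m+n, m) assignments
    of the pooled values to the first group; returns (t_obs, p)."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    z = x + y
    m, n = len(x), len(y)
    t_obs = abs(sum(x) / m - sum(y) / n)
    count = 0
    total = 0
    for combo in combinations(range(m + n), m):
        xs = [z[i] for i in combo]
        ys = [z[i] for i in range(m + n) if i not in combo]
        t = abs(sum(xs) / m - sum(ys) / n)
        if t >= t_obs - 1e-12:
            count += 1
        total += 1
    return t_obs, count / total
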