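"""Distance metrics between consecutive connectivity matrices.

Seven metrics quantify how a brain network changes from one window to the
next.  Three are element-wise norms of the matrix difference (Manhattan,
Frobenius, Chebyshev), two are spectral (nuclear norm of the difference and
the Euclidean distance between sorted eigenvalue spectra), and two come from
persistent graph homology on the weighted complete graph defined by a
connectivity matrix.

Persistent graph homology here uses the graph filtration that deletes edges
with weight <= a rising threshold.  As the threshold rises, connected
components are born and independent cycles die; for a complete graph on M
nodes the component births are exactly the M-1 edge weights of a maximum
spanning tree and the cycle deaths are the remaining 1 + M(M-3)/2 edge
weights.  The p-Wasserstein distance between two such summaries pairs the
l-th smallest value of one multiset with the l-th smallest of the other
(equal cardinality is guaranteed by equal region counts):

    D_p(x, y) = (sum_l |x_(l) - y_(l)|**p) ** (1/p)

Element-wise norms follow the printed sum-over-all-(i, j) convention, so each
undirected edge contributes twice to Manhattan and Frobenius; monotone
rescalings of a metric leave the downstream permutation p-values unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree

from ._errors import ConfigError, DataError
from .connectivity import ConnectivityMatrix, DFCSequence

__all__ = [
    "METRIC_NAMES",
    "MetricSpec",
    "PersistenceSummary",
    "DistanceSeries",
    "elementwise_distance",
    "nuclear_distance",
    "spectral_distance",
    "persistence_decompose",
    "wasserstein_distance",
    "distance_series",
]

METRIC_NAMES = (
    "manhattan",
    "frobenius",
    "chebyshev",
    "nuclear",
    "spectral",
    "wasserstein0",
    "wasserstein1",
)

_ELEMENTWISE = ("manhattan", "frobenius", "chebyshev")


@dataclass(frozen=True)
class MetricSpec:
    """A named distance metric; ``wasserstein_order_p`` only affects the two
    persistence-based metrics."""

    name: str
    wasserstein_order_p: float = 2.0

    def __post_init__(self) -> None:
        if self.name not in METRIC_NAMES:
            raise ConfigError(
                f"unknown metric {self.name!r}; choose from {METRIC_NAMES}"
            )
        if not np.isfinite(self.wasserstein_order_p) or self.wasserstein_order_p < 1:
            raise ConfigError("wasserstein_order_p must be finite and >= 1")


@dataclass
class PersistenceSummary:
    """Birth values of connected components and death values of cycles for
    one matrix's graph filtration, each sorted ascending."""

    births: np.ndarray
    deaths: np.ndarray

    @property
    def n_regions(self) -> int:
        return len(self.births) + 1


@dataclass
class DistanceSeries:
    """Distances between successive matrices of one subject's dFC sequence."""

    values: np.ndarray
    metric_name: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DataError("distance series must be 1-D")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise DataError("distance series values must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.values)


def _as_array(mat: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(mat, ConnectivityMatrix):
        return mat.entries
    return np.asarray(mat, dtype=float)


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    A, B = _as_array(a), _as_array(b)
    if A.shape != B.shape:
        raise DataError(f"matrix dimension mismatch: {A.shape} vs {B.shape}")
    return A, B


def elementwise_distance(a, b, kind: str) -> float:
    """Manhattan, Frobenius or Chebyshev distance over all matrix entries.

    The sums run over the full matrix, so each symmetric off-diagonal pair is
    counted twice (the diagonal contributes nothing for hollow matrices).
    """
    if kind not in _ELEMENTWISE:
        raise ConfigError(f"kind must be one of {_ELEMENTWISE}, got {kind!r}")
    A, B = _pair(a, b)
    diff = A - B
    if kind == "manhattan":
        return float(np.abs(diff).sum())
    if kind == "frobenius":
        return float(np.sqrt((diff ** 2).sum()))
    return float(np.abs(diff).max())


def nuclear_distance(a, b) -> float:
    """Sum of the singular values of the matrix difference."""
    A, B = _pair(a, b)
    return float(np.linalg.svd(A - B, compute_uv=False).sum())


def spectral_distance(a, b) -> float:
    """Euclidean norm of the difference between the sorted eigenvalue
    spectra of two symmetric matrices (eigenvalues sorted ascending)."""
    A, B = _pair(a, b)
    la = np.sort(np.linalg.eigvalsh(A))
    lb = np.sort(np.linalg.eigvalsh(B))
    return float(np.linalg.norm(la - lb))


def persistence_decompose(mat) -> PersistenceSummary:
    """Split a connectivity matrix's edge weights into component births and
    cycle deaths of its graph filtration.

    The matrix is treated as a complete weighted graph on M nodes
    (zero-weight edges permitted).  Births are the edge weights of a maximum
    spanning tree (|births| = M-1); deaths are all remaining off-diagonal
    weights of the upper triangle (|deaths| = 1 + M(M-3)/2).  The birth and
    death *multisets* are invariant to spanning-tree tie-breaking.
    """
    C = _as_array(mat)
    m = C.shape[0]
    if C.ndim != 2 or C.shape[1] != m:
        raise DataError("connectivity matrix must be square")
    if m < 3:
        raise DataError("persistence decomposition needs M >= 3 (no cycles below)")
    # Max spanning tree via min spanning tree on shifted costs 2 - w; weights
    # lie in [0, 1] so every cost is positive and every edge is present.
    cost = 2.0 - C
    np.fill_diagonal(cost, 0.0)
    tree = minimum_spanning_tree(csr_matrix(cost)).tocoo()
    if len(tree.data) != m - 1:
        raise DataError("graph is not connected in the filtration sense")
    births = np.sort(C[tree.row, tree.col])
    in_tree = np.zeros((m, m), dtype=bool)
    in_tree[np.minimum(tree.row, tree.col), np.maximum(tree.row, tree.col)] = True
    iu, ju = np.triu_indices(m, 1)
    deaths = np.sort(C[iu, ju][~in_tree[iu, ju]])
    assert len(deaths) == 1 + m * (m - 3) // 2
    return PersistenceSummary(births=births, deaths=deaths)


def wasserstein_distance(a, b, dim: int = 0, p: float = 2.0) -> float:
    """p-Wasserstein distance between the persistence summaries of two
    matrices, with the sorted-bijection (order-matched) pairing.

    ``dim=0`` matches component births, ``dim=1`` matches cycle deaths.
    """
    if dim not in (0, 1):
        raise ConfigError("dim must be 0 (components) or 1 (cycles)")
    if not np.isfinite(p) or p < 1:
        raise ConfigError("wasserstein order p must be finite and >= 1")
    A, B = _pair(a, b)
    sa, sb = persistence_decompose(A), persistence_decompose(B)
    x = sa.births if dim == 0 else sa.deaths
    y = sb.births if dim == 0 else sb.deaths
    return _sorted_wasserstein(x, y, p)


def _sorted_wasserstein(x: np.ndarray, y: np.ndarray, p: float) -> float:
    diffs = np.abs(np.sort(x) - np.sort(y))
    return float((diffs ** p).sum() ** (1.0 / p))


def distance_series(
    seq: DFCSequence,
    spec: MetricSpec | str,
    _summaries: list[PersistenceSummary] | None = None,
) -> DistanceSeries:
    """Distances between successive matrices: values[t] = D(C_{t+1}, C_{t+2}).

    For the persistence-based metrics, precomputed per-window summaries may
    be supplied (``_summaries``) so that a pipeline computing both homology
    dimensions decomposes each matrix only once.
    """
    if isinstance(spec, str):
        spec = MetricSpec(spec)
    data = seq.matrices
    if len(data) < 2:
        raise DataError("need at least 2 matrices to form a distance series")
    name = spec.name
    if name in _ELEMENTWISE:
        diff = data[1:] - data[:-1]
        if name == "manhattan":
            vals = np.abs(diff).sum(axis=(1, 2))
        elif name == "frobenius":
            vals = np.sqrt((diff ** 2).sum(axis=(1, 2)))
        else:
            vals = np.abs(diff).max(axis=(1, 2))
    elif name == "nuclear":
        vals = np.linalg.svd(data[1:] - data[:-1], compute_uv=False).sum(axis=1)
    elif name == "spectral":
        lam = np.sort(np.linalg.eigvalsh(data), axis=1)
        vals = np.linalg.norm(lam[1:] - lam[:-1], axis=1)
    else:
        dim = 0 if name == "wasserstein0" else 1
        summaries = _summaries or [persistence_decompose(C) for C in data]
        if len(summaries) != len(data):
            raise DataError("summary count does not match sequence length")
        p = spec.wasserstein_order_p
        vals = np.array(
            [
                _sorted_wasserstein(
                    s.births if dim == 0 else s.deaths,
                    t.births if dim == 0 else t.deaths,
                    p,
                )
                for s, t in zip(summaries[:-1], summaries[1:])
            ]
        )
    return DistanceSeries(vals, metric_name=name, subject_id=seq.subject_id)


def persistence_series(seq: DFCSequence) -> list[PersistenceSummary]:
    """Persistence summaries for every matrix of a sequence (shared input to
    both Wasserstein metrics)."""
    return [persistence_decompose(C) for C in seq.matrices]
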