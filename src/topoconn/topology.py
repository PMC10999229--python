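"""Persistent-homology core: Betti-0 curves under graph filtration.

The connectivity matrix is swept from the empty graph to a connected one by
an edge-density filtration: at threshold ``eps`` the ``ceil(eps * E)``
top-ranked edges (by descending Fisher-z weight, E = n(n-1)/2 unique pairs)
are retained and the number of connected components — the Betti-0 number —
is counted with a union-find structure.  At ``eps = 0`` every node is its own
component (B0 = n, e.g. 264 on the full parcellation); the curve is
non-increasing and reaches 1 once a spanning set of edges has entered.
Density filtration implicitly normalises participant-level differences in the
correlation distribution: only edge *ranks* matter, so any strictly monotone
transformation of the weights (raw r vs Fisher z) leaves the curve unchanged.

The participant-level summary is the trapezoidal area under the B0 curve
(AUC), integrated from ``eps = 0`` to the first threshold where B0 = 1.
Smaller AUC means the network merges into a single component at sparser
densities.

A supplementary correlation-threshold mode sweeps fixed r-cutoffs downward in
steps of 0.01 instead; thresholds are stored as ``1 - r`` so that they ascend.
Negative-weight edges are never needed once a single component has formed:
the curve stops at the first threshold with B0 = 1, so negative cutoffs enter
the grid only while the graph is still disconnected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .connectivity import CLIP_EPS, ConnectivityMatrix
from .errors import DegenerateCurveError, InvalidParameterError

__all__ = [
    "BettiCurve",
    "UnionFind",
    "cutoff_weight",
    "betti0_at",
    "betti0_curve",
    "auc",
]


class UnionFind:
    """Disjoint-set forest with path compression and union by size."""

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n
        self.n_components = n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        self.n_components -= 1
        return True


@dataclass(frozen=True)
class BettiCurve:
    """Filtration thresholds paired with connected-component counts.

    ``thresholds`` ascend (edge-density fractions, or ``1 - r`` in
    correlation mode); ``cutoff_weights`` is the Fisher-z cutoff W at each
    threshold (+inf at the empty graph); ``b0_values`` is non-increasing,
    starts at the node count and — unless ``truncated`` — ends at 1.
    """

    mode: str
    thresholds: np.ndarray
    cutoff_weights: np.ndarray
    b0_values: np.ndarray
    n_nodes: int
    truncated: bool = False

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=float)
        w = np.asarray(self.cutoff_weights, dtype=float)
        b = np.asarray(self.b0_values, dtype=int)
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "cutoff_weights", w)
        object.__setattr__(self, "b0_values", b)
        if not (len(t) == len(w) == len(b)):
            raise InvalidParameterError("curve arrays must have equal length")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise InvalidParameterError("thresholds must be strictly increasing")
        if len(b) >= 2 and np.any(np.diff(b) > 0):
            raise InvalidParameterError("b0 values must be non-increasing")

    def __len__(self) -> int:
        return len(self.thresholds)


def _ranked_edges(m: ConnectivityMatrix):
    """Unique pairs sorted by descending weight, ties by (i, j) node order."""
    n = m.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    w = m.weights[iu, ju]
    # lexsort: primary key last -> sort by -w, then i, then j (deterministic)
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order], w[order]


def _n_retained(density: float, n_pairs: int) -> int:
    if not (0.0 <= density <= 1.0):
        raise InvalidParameterError(f"density must lie in [0, 1], got {density}")
    return min(n_pairs, math.ceil(density * n_pairs))


def cutoff_weight(m: ConnectivityMatrix, density: float) -> float:
    """Fisher-z weight at the given edge-density percentile.

    W is the weight of rank ``ceil(density * E)`` when the E unique edges are
    sorted descending.  ``density = 0`` retains no edges and returns the
    ``+inf`` sentinel; ``density = 1`` returns the minimum off-diagonal
    weight.
    """
    k = _n_retained(density, m.n_pairs)
    if k == 0:
        return math.inf
    _, _, w = _ranked_edges(m)
    return float(w[k - 1])


def betti0_at(m: ConnectivityMatrix, density: float) -> int:
    """Connected-component count of the graph retaining the top-ranked edges.

    Isolated nodes count as components, so the value at density 0 equals the
    node count.
    """
    k = _n_retained(density, m.n_pairs)
    iu, ju, _ = _ranked_edges(m)
    uf = UnionFind(m.n_nodes)
    for i, j in zip(iu[:k], ju[:k]):
        uf.union(int(i), int(j))
    return uf.n_components


def betti0_curve(
    m: ConnectivityMatrix, step: float = 0.01, mode: str = "density"
) -> BettiCurve:
    """Sweep the filtration and record B0 on the regular threshold grid.

    The grid is ``0, step, 2*step, ...``; the sweep stops at the first
    threshold where a single component has formed.  If that never happens
    (possible only with tied weights or in correlation mode on a bounded
    grid) the curve ends at the final threshold with ``truncated=True``.
    """
    if not (0.0 < step <= 1.0):
        raise InvalidParameterError(f"step must lie in (0, 1], got {step}")
    if mode == "density":
        return _density_curve(m, step)
    if mode == "correlation":
        return _correlation_curve(m, step)
    raise InvalidParameterError(f"unknown filtration mode: {mode!r}")


def _density_curve(m: ConnectivityMatrix, step: float) -> BettiCurve:
    n, n_pairs = m.n_nodes, m.n_pairs
    iu, ju, w = _ranked_edges(m)
    uf = UnionFind(n)
    thresholds = [0.0]
    cutoffs = [math.inf]
    b0 = [n]
    k_done = 0
    t = 0
    while b0[-1] > 1:
        t += 1
        eps = t * step
        if eps > 1.0 + 1e-12:
            return BettiCurve(
                "density",
                np.array(thresholds),
                np.array(cutoffs),
                np.array(b0),
                n,
                truncated=True,
            )
        eps = min(eps, 1.0)
        k = _n_retained(eps, n_pairs)
        while k_done < k:
            uf.union(int(iu[k_done]), int(ju[k_done]))
            k_done += 1
        thresholds.append(eps)
        cutoffs.append(float(w[k - 1]) if k else math.inf)
        b0.append(uf.n_components)
        if eps >= 1.0 and uf.n_components > 1:
            return BettiCurve(
                "density",
                np.array(thresholds),
                np.array(cutoffs),
                np.array(b0),
                n,
                truncated=True,
            )
    return BettiCurve(
        "density", np.array(thresholds), np.array(cutoffs), np.array(b0), n
    )


def _correlation_curve(m: ConnectivityMatrix, step: float) -> BettiCurve:
    """Descending r-cutoffs in fixed steps, stored against ascending 1 - r.

    Edges are retained when their correlation exceeds the current cutoff
    ``r = 1 - eps``; cutoff weights are reported on the Fisher-z scale.
    """
    n = m.n_nodes
    iu, ju, w = _ranked_edges(m)  # descending z == descending r
    uf = UnionFind(n)
    r_edges = np.tanh(w)
    thresholds = [0.0]
    cutoffs = [math.inf]
    b0 = [n]
    k_done = 0
    t = 0
    max_t = math.ceil(2.0 / step)  # r sweeps 1 -> -1
    while b0[-1] > 1:
        t += 1
        if t > max_t:
            return BettiCurve(
                "correlation",
                np.array(thresholds),
                np.array(cutoffs),
                np.array(b0),
                n,
                truncated=True,
            )
        eps = t * step
        r_cut = 1.0 - eps
        while k_done < len(r_edges) and r_edges[k_done] > r_cut:
            uf.union(int(iu[k_done]), int(ju[k_done]))
            k_done += 1
        thresholds.append(eps)
        cutoffs.append(float(np.arctanh(np.clip(r_cut, -1 + CLIP_EPS, 1 - CLIP_EPS))))
        b0.append(uf.n_components)
    return BettiCurve(
        "correlation", np.array(thresholds), np.array(cutoffs), np.array(b0), n
    )


def auc(curve: BettiCurve) -> float:
    """Trapezoidal area under the B0 curve up to the first B0 = 1 threshold.

    ``sum_k (eps_{k+1} - eps_k) * (B0_k + B0_{k+1}) / 2`` over consecutive
    grid points; units are components x threshold (density fraction).
    """
    if len(curve) < 2:
        raise DegenerateCurveError(
            f"cannot integrate a curve with {len(curve)} point(s)"
        )
    b = curve.b0_values.astype(float)
    t = curve.thresholds
    hits = np.flatnonzero(b == 1)
    end = (hits[0] + 1) if hits.size else len(b)
    return float(np.trapezoid(b[:end], t[:end]))
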