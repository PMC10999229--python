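"""Graph-theoretic comparators: system segregation and modularity Q.

Both operate on the sparse positive-edge matrix (negative Fisher-z weights
set to zero beforehand; see :func:`topoconn.connectivity.positive_part`).

System segregation quantifies how much more strongly nodes couple within
their own functional network than across networks:

    segregation = (mean_within - mean_between) / mean_within

with means taken over all within-network and all between-network unique node
pairs (diagonal excluded).  Zeroed negative edges count toward the means by
default, so the denominators are the full pair counts W and B.

Modularity Q is Newman's weighted quality index of a partition against a
degree-preserving null model.  Here it is maximised with a deterministic
pipeline — leading-eigenvector recursive bisection, Kernighan-Lin-style
fine-tuning of each split, then greedy node-level sweeps and community
merges until no single move improves Q — so repeated calls return the
identical (Q, partition).  The detected partition is agnostic to any a
priori network assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityMatrix
from .errors import (
    UndefinedModularityError,
    UndefinedSegregationError,
    ValidationError,
)
from .partition import NetworkPartition

__all__ = [
    "SegregationResult",
    "system_segregation",
    "modularity_of_partition",
    "modularity_q",
]

_GAIN_TOL = 1e-12


@dataclass(frozen=True)
class SegregationResult:
    """Mean within- and between-network connectivity and their normalised gap."""

    mean_within: float
    mean_between: float
    segregation: float
    n_within_pairs: int
    n_between_pairs: int


def system_segregation(
    m: ConnectivityMatrix,
    p: NetworkPartition,
    include_zeros: bool = True,
) -> SegregationResult:
    """Whole-brain system segregation of a positive-edge matrix.

    Parameters
    ----------
    m
        Connectivity matrix with negative edges already zeroed.
    p
        Node-to-network assignment covering exactly the matrix nodes.
    include_zeros
        If True (default) zero-weight pairs stay in the within/between
        means; if False the means run over strictly positive pairs only.

    Raises
    ------
    UndefinedSegregationError
        If the mean within-network weight is non-positive.
    """
    if set(p.node_ids) != set(m.node_ids):
        raise ValidationError("partition nodes do not match matrix nodes")
    if p.n_networks < 2:
        raise ValidationError("segregation requires at least 2 networks")
    if np.any(m.weights < 0):
        raise ValidationError(
            "segregation expects a positive-edge matrix; apply positive_part first"
        )
    labels = np.asarray([p.label_of(n) for n in m.node_ids], dtype=object)
    iu, ju = np.triu_indices(m.n_nodes, k=1)
    w = m.weights[iu, ju]
    within = labels[iu] == labels[ju]
    w_in, w_bt = w[within], w[~within]
    if not include_zeros:
        w_in, w_bt = w_in[w_in > 0], w_bt[w_bt > 0]
    if w_in.size == 0:
        raise UndefinedSegregationError("no within-network pairs")
    mean_within = float(w_in.mean())
    mean_between = float(w_bt.mean()) if w_bt.size else 0.0
    if mean_within <= 0:
        raise UndefinedSegregationError(
            f"mean within-network connectivity is {mean_within}; "
            "segregation normalization collapses"
        )
    seg = (mean_within - mean_between) / mean_within
    return SegregationResult(mean_within, mean_between, seg, w_in.size, w_bt.size)


# --------------------------------------------------------------------------
# modularity


def _check_positive(m: ConnectivityMatrix) -> np.ndarray:
    a = np.array(m.weights, dtype=float)
    if np.any(a < 0):
        raise ValidationError(
            "modularity expects a positive-edge matrix; apply positive_part first"
        )
    np.fill_diagonal(a, 0.0)
    if a.sum() <= 0:
        raise UndefinedModularityError("matrix has no positive edge weight")
    return a


def modularity_of_partition(m: ConnectivityMatrix, labels) -> float:
    """Newman weighted modularity of a given node labelling.

    ``Q = sum_c [ in_c / T - (K_c / T)^2 ]`` with T the total weight
    (both edge directions), in_c the within-community weight and K_c the
    community degree sum.  The trivial single-community labelling gives 0.
    """
    a = _check_positive(m)
    labels = np.asarray(labels)
    if labels.shape[0] != m.n_nodes:
        raise ValidationError("one label per node required")
    total = a.sum()
    k = a.sum(axis=1)
    q = 0.0
    for lab in np.unique(labels):
        mask = labels == lab
        q += a[np.ix_(mask, mask)].sum() / total - (k[mask].sum() / total) ** 2
    return float(q)


def _leading_split(b_sub: np.ndarray) -> np.ndarray | None:
    """Sign split from the leading eigenvector of a (generalised) modularity
    matrix; None when the matrix is negative semidefinite (indivisible)."""
    vals, vecs = np.linalg.eigh((b_sub + b_sub.T) / 2.0)
    if vals[-1] <= 1e-12:
        return None
    v = vecs[:, -1]
    s = np.where(v >= 0, 1, -1)
    if np.all(s == s[0]):
        return None
    return s


def _fine_tune_split(b_sub: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan-Lin-style refinement of a two-way split.

    Repeatedly moves every vertex exactly once (greedy order) and keeps the
    best intermediate configuration; deterministic because ties resolve to
    the lowest vertex index.
    """
    s = s.astype(float).copy()
    n = len(s)
    score = float(s @ b_sub @ s)
    improved = True
    while improved:
        improved = False
        trial = s.copy()
        moved = np.zeros(n, dtype=bool)
        best_score, best_state = score, s.copy()
        cur = score
        for _ in range(n):
            # delta of flipping vertex v: -4 s_v (B s)_v + 4 B_vv
            bs = b_sub @ trial
            deltas = -4.0 * trial * bs + 4.0 * np.diag(b_sub)
            deltas[moved] = -np.inf
            v = int(np.argmax(deltas))
            cur += deltas[v]
            trial[v] = -trial[v]
            moved[v] = True
            if cur > best_score + _GAIN_TOL and not (
                np.all(trial == 1) or np.all(trial == -1)
            ):
                best_score, best_state = cur, trial.copy()
        if best_score > score + _GAIN_TOL:
            score, s = best_score, best_state
            improved = True
    return np.where(s >= 0, 1, -1)


def _greedy_sweeps(a: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Deterministic single-node move sweeps (incl. splitting to a new
    singleton community) until no move improves Q."""
    total = a.sum()
    k = a.sum(axis=1)
    labels = labels.copy()
    for _ in range(200):  # safety bound; converges long before
        changed = False
        for v in range(len(labels)):
            comms, inv = np.unique(labels, return_inverse=True)
            s_vc = np.bincount(inv, weights=a[v], minlength=len(comms))
            k_c = np.bincount(inv, weights=k, minlength=len(comms))
            cur = int(inv[v])
            # gain of moving v from its community to candidate c
            gains = 2.0 * (s_vc - s_vc[cur]) / total - (
                2.0 * k[v] * (k_c - (k_c[cur] - k[v]))
            ) / total**2
            gains[cur] = 0.0
            # candidate: empty (new singleton) community
            gain_new = -2.0 * s_vc[cur] / total + (
                2.0 * k[v] * (k_c[cur] - k[v])
            ) / total**2
            best = int(np.argmax(gains))
            if gain_new > gains[best] + _GAIN_TOL:
                labels[v] = labels.max() + 1
                changed = True
            elif gains[best] > _GAIN_TOL:
                labels[v] = comms[best]
                changed = True
        if not changed:
            break
    return labels


def _merge_sweeps(m: ConnectivityMatrix, labels: np.ndarray) -> np.ndarray:
    """Merge community pairs while any merge improves Q (deterministic)."""
    labels = labels.copy()
    while True:
        comms = np.unique(labels)
        if len(comms) < 2:
            break
        base = modularity_of_partition(m, labels)
        best_gain, best_pair = _GAIN_TOL, None
        for i in range(len(comms)):
            for j in range(i + 1, len(comms)):
                trial = labels.copy()
                trial[trial == comms[j]] = comms[i]
                gain = modularity_of_partition(m, trial) - base
                if gain > best_gain:
                    best_gain, best_pair = gain, (comms[i], comms[j])
        if best_pair is None:
            break
        labels[labels == best_pair[1]] = best_pair[0]
    return labels


def modularity_q(m: ConnectivityMatrix) -> tuple[float, NetworkPartition]:
    """Deterministic modularity maximisation on the positive-edge matrix.

    Returns the maximised Q together with the detected community partition
    (labels ``c0, c1, ...`` in node order of first appearance).  Repeated
    calls on the same matrix return identical results.
    """
    a = _check_positive(m)
    n = m.n_nodes
    total = a.sum()
    k = a.sum(axis=1)
    b_full = a - np.outer(k, k) / total

    labels = np.zeros(n, dtype=int)
    next_label = 1
    stack = [0]
    while stack:
        lab = stack.pop()
        idx = np.flatnonzero(labels == lab)
        if len(idx) < 2:
            continue
        # generalised modularity matrix of the subgroup
        b_sub = b_full[np.ix_(idx, idx)].copy()
        b_sub -= np.diag(b_sub.sum(axis=1))
        s = _leading_split(b_sub)
        if s is None:
            continue
        s = _fine_tune_split(b_sub, s)
        if float(s @ b_sub @ s) <= _GAIN_TOL:
            continue
        labels[idx[s < 0]] = next_label
        stack.extend([lab, next_label])
        next_label += 1

    labels = _greedy_sweeps(a, labels)
    labels = _merge_sweeps(m, labels)
    labels = _greedy_sweeps(a, labels)

    # canonical labels in node order
    remap: dict[int, str] = {}
    final = []
    for lab in labels:
        if lab not in remap:
            remap[lab] = f"c{len(remap)}"
        final.append(remap[lab])
    q = modularity_of_partition(m, np.asarray(final, dtype=object))
    return q, NetworkPartition(m.node_ids, tuple(final))
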