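"""Markov clustering (MCL) of weighted undirected graphs.

Alternates random-walk expansion (matrix squaring) and inflation
(entrywise power followed by column renormalization) on a
column-stochastic matrix until the flow stabilizes, then reads clusters
off the attractor rows.  Small entries are pruned between iterations to
keep the matrix sparse.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["mcl", "MCLResult"]


class MCLResult:
    """Partition produced by :func:`mcl` plus convergence diagnostics."""

    def __init__(self, clusters: list[list[str]], n_iterations: int, converged: bool):
        self.clusters = clusters
        self.n_iterations = n_iterations
        self.converged = converged

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self):
        return len(self.clusters)


def _normalize_columns(m: sp.csc_matrix) -> sp.csc_matrix:
    sums = np.asarray(m.sum(axis=0)).ravel()
    sums[sums == 0.0] = 1.0
    return m.multiply(1.0 / sums).tocsc()


def _prune(m: sp.csc_matrix, threshold: float) -> sp.csc_matrix:
    """Zero entries below threshold, but never empty a column."""
    m = m.tocsc()
    keep = m.data >= threshold
    # protect each column's maximum so no node loses all flow
    for j in range(m.shape[1]):
        lo, hi = m.indptr[j], m.indptr[j + 1]
        if lo == hi:
            continue
        col = m.data[lo:hi]
        keep[lo + int(np.argmax(col))] = True
    m.data[~keep] = 0.0
    m.eliminate_zeros()
    return m


def mcl(
    graph,
    inflation: float = 2.0,
    max_iter: int = 200,
    tolerance: float = 1e-8,
    prune_threshold: float = 1e-5,
) -> MCLResult:
    """Cluster a weighted undirected graph with Markov clustering.

    Parameters
    ----------
    graph : networkx.Graph
        Undirected graph; edge attribute ``weight`` (default 1.0) must be
        positive.  Self-loops are added internally with weight equal to
        the node's maximum incident weight (1.0 for isolated nodes),
        a standard regularization that guarantees convergence.
    inflation : float
        Inflation exponent; must exceed 1.  Higher values give finer
        clusters.
    max_iter, tolerance : int, float
        Iteration stops when the largest entrywise change falls below
        ``tolerance`` or after ``max_iter`` rounds.
    prune_threshold : float
        Entries below this are zeroed after each inflation (each column's
        maximum is always retained).

    Returns
    -------
    MCLResult
        Clusters as lists of node labels; every node appears in exactly
        one cluster.  A node attracted by several clusters is assigned to
        the one containing the lexicographically smallest member.
    """
    if inflation <= 1:
        raise ValueError(f"inflation must exceed 1, got {inflation}")
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return MCLResult([], 0, True)
    index = {v: i for i, v in enumerate(nodes)}

    rows, cols, vals = [], [], []
    max_incident = np.zeros(n)
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w <= 0:
            raise ValueError(f"edge ({u!r}, {v!r}) has non-positive weight {w}")
        if u == v:
            continue  # replaced by the regularizing self-loop below
        i, j = index[u], index[v]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
        max_incident[i] = max(max_incident[i], w)
        max_incident[j] = max(max_incident[j], w)
    loops = np.where(max_incident > 0, max_incident, 1.0)
    rows += list(range(n))
    cols += list(range(n))
    vals += list(loops)

    m = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    m = _normalize_columns(m)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        expanded = (m @ m).tocsc()
        inflated = expanded.copy()
        inflated.data = np.power(inflated.data, inflation)
        inflated = _normalize_columns(inflated)
        inflated = _prune(inflated, prune_threshold)
        inflated = _normalize_columns(inflated)
        diff = abs(inflated - m).max() if (inflated - m).nnz else 0.0
        m = inflated
        if diff < tolerance:
            converged = True
            break

    clusters = _extract_clusters(m, nodes)
    return MCLResult(clusters, it, converged)


def _extract_clusters(m: sp.csc_matrix, nodes: list[str]) -> list[list[str]]:
    """Read the partition off attractor rows; break overlaps deterministically."""
    m = m.tocsr()
    n = len(nodes)
    attractors = np.flatnonzero(m.diagonal() > 0)
    raw: set[tuple[int, ...]] = set()
    for a in attractors:
        members = tuple(sorted(m.indices[m.indptr[a]:m.indptr[a + 1]]))
        if members:
            raw.add(members)
    # a node attracted by several clusters goes with the cluster whose
    # smallest member id is lexicographically least
    sorted_clusters = sorted(raw, key=lambda c: (nodes[min(c, key=lambda i: nodes[i])], c))
    assigned: dict[int, int] = {}
    for ci, cluster in enumerate(sorted_clusters):
        for node_i in cluster:
            if node_i not in assigned:
                assigned[node_i] = ci
    out: dict[int, list[str]] = {}
    for node_i, ci in assigned.items():
        out.setdefault(ci, []).append(nodes[node_i])
    clusters = [sorted(members) for members in out.values()]
    # nodes never reached by an attractor (should not occur) become singletons
    seen = {v for c in clusters for v in c}
    clusters += [[v] for v in nodes if v not in seen]
    return sorted(clusters, key=lambda c: c[0])
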