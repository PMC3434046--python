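"""Independent dense-numpy Markov clustering, used only as a cross-check
oracle against the sparse engine in qortho.mcl.  Same algorithm semantics
(max-incident self-loops, entrywise inflation, column-max-protected
pruning, attractor read-off), written from scratch on dense arrays."""

import numpy as np


def reference_mcl(graph, inflation=2.0, max_iter=200, tolerance=1e-8, prune_threshold=1e-5):
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return []
    pos = {v: i for i, v in enumerate(nodes)}

    a = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        if u == v:
            continue
        w = float(data.get("weight", 1.0))
        a[pos[u], pos[v]] = a[pos[v], pos[u]] = w
    loops = a.max(axis=0)
    loops[loops == 0.0] = 1.0
    np.fill_diagonal(a, loops)

    m = a / a.sum(axis=0)
    for _ in range(max_iter):
        nxt = np.linalg.matrix_power(m, 2) ** inflation
        nxt = nxt / nxt.sum(axis=0)
        for j in range(n):
            col = nxt[:, j]
            keep = col >= prune_threshold
            keep[int(np.argmax(col))] = True
            col[~keep] = 0.0
        nxt = nxt / nxt.sum(axis=0)
        done = np.abs(nxt - m).max() < tolerance
        m = nxt
        if done:
            break

    clusters = set()
    for i in range(n):
        if m[i, i] > 0:
            members = tuple(np.flatnonzero(m[i, :]))
            if members:
                clusters.add(members)
    ordered = sorted(clusters, key=lambda c: (nodes[min(c, key=lambda i: nodes[i])], c))
    owner = {}
    for ci, cluster in enumerate(ordered):
        for i in cluster:
            owner.setdefault(i, ci)
    grouped = {}
    for i, ci in owner.items():
        grouped.setdefault(ci, []).append(nodes[i])
    out = [sorted(c) for c in grouped.values()]
    out += [[nodes[i]] for i in range(n) if i not in owner]
    return sorted(out, key=lambda c: c[0])
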