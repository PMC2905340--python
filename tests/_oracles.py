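"""Independent brute-force oracles for small networks.

Deliberately naive implementations (dynamic programming over the full
distance matrix, exhaustive neighbour-pair enumeration, label propagation)
used only to check the package's graph statistics on small random
digraphs.  They share no code path with the implementation.
"""
from __future__ import annotations

import math


def floyd_warshall(nodes, edges, directed=True):
    """Dense all-pairs shortest paths; dict-of-dicts with math.inf."""
    nodes = list(nodes)
    dist = {u: {v: math.inf for v in nodes} for u in nodes}
    for u in nodes:
        dist[u][u] = 0
    for s, t, _ in edges:
        dist[s][t] = min(dist[s][t], 1)
        if not directed:
            dist[t][s] = min(dist[t][s], 1)
    for k in nodes:
        for i in nodes:
            dik = dist[i][k]
            if dik is math.inf:
                continue
            for j in nodes:
                alt = dik + dist[k][j]
                if alt < dist[i][j]:
                    dist[i][j] = alt
    return dist


def path_stats_oracle(nodes, edges, directed=True):
    """(char_path_length, diameter, finite_pair_count) over ordered pairs."""
    dist = floyd_warshall(nodes, edges, directed)
    finite = [
        dist[u][v]
        for u in nodes
        for v in nodes
        if u != v and dist[u][v] is not math.inf
    ]
    if not finite:
        return None, None, 0
    return sum(finite) / len(finite), max(finite), len(finite)


def closeness_oracle(nodes, edges, label):
    dist = floyd_warshall(nodes, edges, directed=True)
    reach = [d for v, d in dist[label].items() if v != label and d is not math.inf]
    if not reach:
        return 0.0
    return 1.0 / (sum(reach) / len(reach))


def clustering_oracle(nodes, edges, label):
    """2nI/(kI(kI-1)) by exhaustive neighbour-pair enumeration."""
    nbrs = set()
    for s, t, _ in edges:
        if s == label and t != label:
            nbrs.add(t)
        if t == label and s != label:
            nbrs.add(s)
    k = len(nbrs)
    if k < 2:
        return 0.0
    pairs = {(s, t) for s, t, _ in edges}
    nb = sorted(nbrs)
    links = 0
    for i in range(k):
        for j in range(i + 1, k):
            u, w = nb[i], nb[j]
            if (u, w) in pairs or (w, u) in pairs:
                links += 1
    return 2.0 * links / (k * (k - 1))


def components_oracle(nodes, edges):
    """Weak components by iterated label propagation on symmetrized edges."""
    label = {v: v for v in nodes}
    sym = [(s, t) for s, t, _ in edges] + [(t, s) for s, t, _ in edges]
    changed = True
    while changed:
        changed = False
        for s, t in sym:
            if label[t] < label[s]:
                label[s] = label[t]
                changed = True
            # propagate through chains until stable
    groups = {}
    for v in nodes:
        # walk to the representative
        rep = v
        while label[rep] != rep:
            rep = label[rep]
        groups.setdefault(rep, set()).add(v)
    return sorted((frozenset(g) for g in groups.values()), key=lambda g: (-len(g), min(g)))


def degree_counts_oracle(nodes, edges, mode):
    """Per-node degree by direct edge counting, then a histogram."""
    deg = {v: 0 for v in nodes}
    for s, t, _ in edges:
        if mode in ("out", "total"):
            deg[s] += 1
        if mode in ("in", "total"):
            deg[t] += 1
    hist = {}
    n_zero = 0
    for k in deg.values():
        if k == 0:
            n_zero += 1
        else:
            hist[k] = hist.get(k, 0) + 1
    return sorted(hist.items()), n_zero
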