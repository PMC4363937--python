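"""Independent brute-force oracles used by the test suite.

Each oracle deliberately avoids the code paths it checks: the running-sum
walk is a literal step-by-step loop, betweenness is exhaustive shortest-path
enumeration over an adjacency dict, and characteristic path length goes
through scipy's Floyd–Warshall on a dense matrix.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
from scipy.sparse.csgraph import floyd_warshall


def walk_es(scores, hit_mask, weight_p):
    """Literal O(N) enrichment-score walk; returns (es, running_sum list)."""
    scores = list(scores)
    n = len(scores)
    n_hits = sum(hit_mask)
    weights = [abs(s) ** weight_p for s, h in zip(scores, hit_mask) if h]
    total = sum(weights)
    if total == 0:
        weights = [1.0] * n_hits
        total = float(n_hits)
    miss = 1.0 / (n - n_hits)
    running, cum, wi = [], 0.0, 0
    for h in hit_mask:
        if h:
            cum += weights[wi] / total
            wi += 1
        else:
            cum -= miss
        running.append(cum)
    es = max(running, key=abs)
    return es, running


def brute_betweenness(adj: dict) -> dict:
    """Betweenness by explicit enumeration of every shortest path.

    ``adj`` maps node -> set of neighbors.  For each unordered pair (s, t),
    all shortest s-t paths are enumerated by depth-first search constrained
    to BFS distance layers; each interior vertex of each path gets
    1/(number of shortest s-t paths).
    """
    nodes = sorted(adj)
    btw = {v: 0.0 for v in nodes}

    def bfs_dist(src):
        dist = {src: 0}
        q = deque([src])
        while q:
            u = q.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    q.append(w)
        return dist

    for s, t in itertools.combinations(nodes, 2):
        dist = bfs_dist(s)
        if t not in dist:
            continue
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for w in adj[u]:
                if w in dist and dist[w] == dist[u] + 1 and dist[w] <= dist[t]:
                    extend(path + [w])

        extend([s])
        for p in paths:
            for interior in p[1:-1]:
                btw[interior] += 1.0 / len(paths)
    return btw


def fw_char_path_length(adj: dict) -> float:
    """Characteristic path length of the largest component via Floyd–Warshall."""
    nodes = sorted(adj)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    mat = np.full((n, n), np.inf)
    np.fill_diagonal(mat, 0.0)
    for v, nbrs in adj.items():
        for w in nbrs:
            mat[idx[v], idx[w]] = 1.0
    d = floyd_warshall(mat, directed=False)
    # largest component = row with most finite entries
    finite_counts = np.isfinite(d).sum(axis=1)
    comp_mask = np.isfinite(d[np.argmax(finite_counts)])
    sub = d[np.ix_(comp_mask, comp_mask)]
    m = sub.shape[0]
    if m < 2:
        return 0.0
    triu = sub[np.triu_indices(m, k=1)]
    return float(triu.mean())


def graph_to_adj(g) -> dict:
    return {v: set(g.neighbors(v)) for v in g.nodes}
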