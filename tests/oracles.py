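"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the code paths they verify: betweenness is
computed by explicit shortest-path enumeration (not Brandes), and the
hypergeometric tail by exact binomial-coefficient summation (not scipy).
"""

from __future__ import annotations

from collections import deque
from math import comb


def bfs_distances(adj: dict, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def enumerate_shortest_paths(adj: dict, s, t, dist_to_t: dict):
    """All shortest s-t paths, by descending the BFS distance field."""
    if t not in dist_to_t or s not in dist_to_t:
        return []
    paths = []

    def walk(u, acc):
        if u == t:
            paths.append(acc)
            return
        for v in adj[u]:
            if v in dist_to_t and dist_to_t[v] == dist_to_t[u] - 1:
                walk(v, acc + [v])

    walk(s, [s])
    return paths


def betweenness_oracle(nodes, edges, normalized=True):
    """Endpoint-excluded betweenness by exhaustive shortest-path listing.

    Normalization divides by (N-1)(N-2)/2 with N the whole-graph order,
    also for disconnected graphs; N < 3 yields all zeros.
    """
    nodes = list(nodes)
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    raw = {n: 0.0 for n in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            dist_to_t = bfs_distances(adj, t)
            paths = enumerate_shortest_paths(adj, s, t, dist_to_t)
            if not paths:
                continue
            sigma = len(paths)
            for n in nodes:
                if n in (s, t):
                    continue
                through = sum(1 for p in paths if n in p)
                raw[n] += through / sigma
    n_nodes = len(nodes)
    if not normalized or n_nodes < 3:
        return raw if not normalized else {n: 0.0 if n_nodes < 3 else raw[n]
                                           for n in nodes}
    divisor = (n_nodes - 1) * (n_nodes - 2) / 2.0
    return {n: raw[n] / divisor for n in nodes}


def hypergeom_upper_oracle(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by exact summation of hypergeometric point masses."""
    total = comb(N, n)
    hits = sum(comb(K, i) * comb(N - K, n - i)
               for i in range(k, min(K, n) + 1))
    return hits / total


def bh_oracle(pvals):
    """Literal step-up definition, quadratic time."""
    m = len(pvals)
    indexed = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(indexed, start=1):
        candidates = [pvals[j] * m / (r + 1)
                      for r, j in enumerate(indexed) if r + 1 >= rank_pos]
        q[i] = min(1.0, min(candidates))
    return q
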