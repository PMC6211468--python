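"""Independent brute-force oracles used to validate the implementation.

Deliberately written from first principles (BFS + pair counting, iterative
pruning, exhaustive draw enumeration, factorial identities) and sharing no
code path with the package under test.
"""

from __future__ import annotations

import itertools
import math
from collections import deque


def bfs_levels(adj: dict, source):
    """Distances and shortest-path counts from one source (plain BFS)."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                queue.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def adjacency(graph) -> dict:
    return {v: set(graph.neighbors(v)) for v in graph.nodes}


def brute_degree(graph) -> dict:
    adj = adjacency(graph)
    return {v: len(neigh) for v, neigh in adj.items()}


def brute_betweenness(graph, normalized: bool = True) -> dict:
    """Pair-by-pair fractional shortest-path counting (not Brandes)."""
    adj = adjacency(graph)
    nodes = list(adj)
    n = len(nodes)
    dist = {}
    sigma = {}
    for s in nodes:
        dist[s], sigma[s] = bfs_levels(adj, s)
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if t not in dist[s]:
            continue
        d_st = dist[s][t]
        total = sigma[s][t]
        for v in nodes:
            if v == s or v == t or v not in dist[s] or t not in dist[v]:
                continue
            if dist[s][v] + dist[v][t] == d_st:
                bc[v] += sigma[s][v] * sigma[v][t] / total
    if normalized:
        if n < 3:
            return {v: 0.0 for v in nodes}
        denom = (n - 1) * (n - 2) / 2
        bc = {v: x / denom for v, x in bc.items()}
    return bc


def brute_closeness_wf(graph) -> dict:
    """Component-restricted closeness with Wasserman-Faust scaling."""
    adj = adjacency(graph)
    n = len(adj)
    out = {}
    for v in adj:
        dist, _ = bfs_levels(adj, v)
        r = len(dist)  # component size (includes v)
        total = sum(dist.values())
        if r <= 1 or total == 0 or n <= 1:
            out[v] = 0.0
        else:
            out[v] = ((r - 1) / (n - 1)) * ((r - 1) / total)
    return out


def brute_coreness(graph) -> dict:
    """Shell index via literal iterative pruning at increasing k."""
    adj = {v: set(neigh) for v, neigh in adjacency(graph).items()}
    coreness = {v: 0 for v in adj}
    k = 1
    while adj:
        while True:
            drop = [v for v, neigh in adj.items() if len(neigh) < k]
            if not drop:
                break
            for v in drop:
                for u in adj[v]:
                    adj[u].discard(v)
                del adj[v]
        for v in adj:
            coreness[v] = k
        k += 1
    return coreness


def enum_hypergeom_tail_table(N: int, K: int, n: int) -> dict[int, float]:
    """Upper-tail P(X >= k) for every k, by enumerating all C(N, n) draws."""
    successes = set(range(K))
    counts: dict[int, int] = {}
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        k = len(successes.intersection(draw))
        counts[k] = counts.get(k, 0) + 1
    tails = {}
    for k in range(0, min(K, n) + 2):
        tails[k] = sum(c for kk, c in counts.items() if kk >= k) / total
    return tails


def fisher_one_sided_greater(k: int, N: int, K: int, n: int) -> float:
    """One-sided Fisher exact p of [[k, n-k], [K-k, N-K-n+k]] from factorials."""
    p = 0.0
    denom = math.comb(N, n)
    for i in range(k, min(K, n) + 1):
        if n - i > N - K:
            continue
        p += math.comb(K, i) * math.comb(N - K, n - i) / denom
    return p


def bh_step_up(p_values):
    """Hand Benjamini-Hochberg: q_(i) = min_{j>=i} p_(j) * m / j, order restored."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p_values[idx] * m / rank)
        q_sorted[rank - 1] = running
    q = [0.0] * m
    for rank, idx in enumerate(order):
        q[idx] = q_sorted[rank]
    return q
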