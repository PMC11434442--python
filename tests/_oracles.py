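"""Independent brute-force oracles used to verify package computations.

Everything here is written from first principles (BFS, explicit path
enumeration, set-partition search, textbook formulas) and deliberately avoids
the code paths under test.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def bfs_distances(adj: dict, source):
    """Unweighted shortest-path distances from source via plain BFS."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def adjacency(edges, nodes):
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def brute_closeness(edges, nodes):
    """Wasserman-Faust component-scaled closeness, from BFS distances."""
    adj = adjacency(edges, nodes)
    n = len(nodes)
    out = {}
    for v in nodes:
        dist = bfs_distances(adj, v)
        r = len(dist)  # component size
        total = sum(dist.values())
        if r <= 1 or total == 0 or n <= 1:
            out[v] = 0.0
        else:
            out[v] = ((r - 1) / (n - 1)) * ((r - 1) / total)
    return out


def _all_shortest_paths(adj, s, t):
    """Every shortest simple path s->t by exhaustive DFS (small graphs only)."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    target_len = dist[t]
    paths = []

    def dfs(path):
        u = path[-1]
        if u == t:
            if len(path) - 1 == target_len:
                paths.append(tuple(path))
            return
        if len(path) - 1 >= target_len:
            return
        for v in adj[u]:
            if v not in path:
                dfs(path + [v])

    dfs([s])
    return paths


def brute_betweenness(edges, nodes):
    """Betweenness by explicit shortest-path enumeration, normalized by
    2/((n-1)(n-2)) for undirected graphs; zeros when n < 3."""
    adj = adjacency(edges, nodes)
    n = len(nodes)
    raw = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            raw[v] += through / len(paths)
    if n < 3:
        return {v: 0.0 for v in nodes}
    norm = 2.0 / ((n - 1) * (n - 2))
    return {v: raw[v] * norm for v in nodes}


def brute_clustering(edges, nodes):
    """Local clustering 2*tri/(k(k-1)) by direct triangle counting."""
    adj = adjacency(edges, nodes)
    out = {}
    for v in nodes:
        k = len(adj[v])
        if k < 2:
            out[v] = 0.0
            continue
        tri = sum(
            1 for a, b in itertools.combinations(adj[v], 2) if b in adj[a]
        )
        out[v] = 2.0 * tri / (k * (k - 1))
    return out


def brute_degrees(edges, nodes):
    adj = adjacency(edges, nodes)
    return {v: len(adj[v]) for v in nodes}


def brute_modularity_pairwise(edges, nodes, membership):
    """Q by the pairwise sum (A_ij - k_i k_j / 2m) delta(c_i, c_j) / 2m."""
    adj = adjacency(edges, nodes)
    m = len(edges)
    if m == 0:
        return 0.0
    k = {v: len(adj[v]) for v in nodes}
    q = 0.0
    for i in nodes:
        for j in nodes:
            if membership[i] != membership[j]:
                continue
            a_ij = 1.0 if j in adj[i] else 0.0
            q += a_ij - k[i] * k[j] / (2.0 * m)
    return q / (2.0 * m)


def set_partitions(items):
    """All set partitions of a list (Bell-number many; keep n small)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1:]
        yield [[first]] + partition


def exhaustive_max_modularity(edges, nodes):
    """Best modularity over every partition (n <= 8 only)."""
    best_q = -np.inf
    best = None
    for partition in set_partitions(list(nodes)):
        membership = {}
        for i, block in enumerate(partition):
            for v in block:
                membership[v] = i
        q = brute_modularity_pairwise(edges, nodes, membership)
        if q > best_q:
            best_q = q
            best = [set(b) for b in partition]
    return best_q, best


def spearman_textbook(x, y):
    """1 - 6*sum(d^2)/(n(n^2-1)) on tie-free data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    rx = np.empty(n)
    rx[np.argsort(x)] = np.arange(1, n + 1)
    ry = np.empty(n)
    ry[np.argsort(y)] = np.arange(1, n + 1)
    d = rx - ry
    return 1.0 - 6.0 * float(np.sum(d * d)) / (n * (n * n - 1))


def bh_reference(p_values):
    """Literal Benjamini-Hochberg step-up loop."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        value = min(1.0, p[i] * m / rank)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def adjusted_rand_index(labels_a: dict, labels_b: dict) -> float:
    """ARI from the contingency table, written out longhand."""
    keys = sorted(labels_a)
    a_vals = [labels_a[k] for k in keys]
    b_vals = [labels_b[k] for k in keys]
    n = len(keys)

    def comb2(x):
        return x * (x - 1) / 2.0

    from collections import Counter

    contingency = Counter(zip(a_vals, b_vals))
    a_counts = Counter(a_vals)
    b_counts = Counter(b_vals)
    sum_comb = sum(comb2(c) for c in contingency.values())
    sum_a = sum(comb2(c) for c in a_counts.values())
    sum_b = sum(comb2(c) for c in b_counts.values())
    expected = sum_a * sum_b / comb2(n) if n > 1 else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return (sum_comb - expected) / (max_index - expected)
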