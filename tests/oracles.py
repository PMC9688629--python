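"""Brute-force reference implementations used only as test oracles.

Deliberately naive (enumeration, O(n^3) loops) and independent of the
package's implementation paths.
"""

from __future__ import annotations

import itertools

import numpy as np


def triangle_clustering(adj: np.ndarray) -> np.ndarray:
    """C_i by explicit triangle enumeration."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        t = sum(1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b])
        out[i] = 2.0 * t / (k * (k - 1))
    return out


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def mean_inverse_distance(dist: np.ndarray) -> float:
    n = dist.shape[0]
    acc = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]) and dist[i, j] > 0:
                acc += 1.0 / dist[i, j]
    return acc / (n * (n - 1))


def path_enumeration_betweenness(adj: np.ndarray) -> np.ndarray:
    """Betweenness by enumerating every simple path between every pair,
    keeping the shortest, and crediting interior nodes fractionally."""
    n = adj.shape[0]
    bc = np.zeros(n)

    def simple_paths(s, t):
        stack = [(s, [s])]
        while stack:
            node, path = stack.pop()
            if node == t:
                yield path
                continue
            for nxt in range(n):
                if adj[node, nxt] and nxt not in path:
                    stack.append((nxt, path + [nxt]))

    for s, t in itertools.combinations(range(n), 2):
        paths = list(simple_paths(s, t))
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == shortest]
        for p in geodesics:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(geodesics)
    return bc


def partitions(items):
    """All set partitions (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def newman_girvan_q(adj: np.ndarray, partition) -> float:
    m2 = adj.sum()  # 2m
    if m2 == 0:
        return 0.0
    deg = adj.sum(axis=1)
    q = 0.0
    for block in partition:
        for i in block:
            for j in block:
                q += adj[i, j] - deg[i] * deg[j] / m2
    return q / m2


def exhaustive_best_modularity(adj: np.ndarray) -> float:
    return max(newman_girvan_q(adj, p) for p in partitions(range(adj.shape[0])))


def random_adjacency(rng: np.random.Generator, n: int,
                     p: float = 0.4) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, 1)
    return a + a.T
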