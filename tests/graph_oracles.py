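"""Brute-force oracles for weighted-graph metrics on tiny graphs (n <= 6).

Everything here works by exhaustive enumeration -- all simple paths for
distances / path counts / betweenness, all triples for clustering, all set
partitions for modularity -- independent of the package's algorithms.
"""

from itertools import permutations

import numpy as np

TIE_RTOL = 1e-12


def _close(a: float, b: float) -> bool:
    return abs(a - b) <= TIE_RTOL * max(1.0, abs(a), abs(b))


def all_simple_paths(W: np.ndarray, s: int, t: int) -> list[list[int]]:
    n = W.shape[0]
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in range(n):
            if W[u, v] > 0 and v not in path:
                path.append(v)
                extend(path)
                path.pop()

    extend([s])
    return paths


def oracle_paths(W: np.ndarray):
    """(dist, counts) by enumerating every simple path between every pair."""
    n = W.shape[0]
    dist = np.full((n, n), np.inf)
    counts = np.zeros((n, n))
    np.fill_diagonal(dist, 0.0)
    np.fill_diagonal(counts, 1.0)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            lengths = [
                sum(1.0 / W[a, b] for a, b in zip(p[:-1], p[1:]))
                for p in all_simple_paths(W, s, t)
            ]
            if not lengths:
                continue
            d = min(lengths)
            dist[s, t] = d
            counts[s, t] = sum(1 for L in lengths if _close(L, d))
    return dist, counts


def oracle_degree(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    return np.array([sum(W[i, j] for j in range(n)) for i in range(n)])


def oracle_clustering(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    C = np.zeros(n)
    for i in range(n):
        t = 0.0
        for j in range(n):
            for h in range(n):
                t += (W[i, j] * W[i, h] * W[j, h]) ** (1.0 / 3.0)
        t /= 2.0
        k = sum(1 for j in range(n) if W[i, j] > 0)
        if k > 1:
            C[i] = 2.0 * t / (k * (k - 1))
    return C


def oracle_path_length(W: np.ndarray) -> np.ndarray:
    dist, _ = oracle_paths(W)
    n = W.shape[0]
    return np.array([sum(dist[i, j] for j in range(n) if j != i) / (n - 1)
                     for i in range(n)])


def oracle_betweenness(W: np.ndarray) -> np.ndarray:
    """Unordered-pair betweenness via path enumeration."""
    n = W.shape[0]
    b = np.zeros(n)
    for h in range(n):
        for j in range(h + 1, n):
            paths = all_simple_paths(W, h, j)
            if not paths:
                continue
            lengths = [
                sum(1.0 / W[a, c] for a, c in zip(p[:-1], p[1:])) for p in paths
            ]
            d = min(lengths)
            shortest = [p for p, L in zip(paths, lengths) if _close(L, d)]
            for i in range(n):
                if i in (h, j):
                    continue
                through = sum(1 for p in shortest if i in p)
                b[i] += through / len(shortest)
    return b / ((n - 1) * (n - 2))


def set_partitions(items: list[int]):
    """All partitions of a set (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for k in range(len(smaller)):
            yield smaller[:k] + [[first] + smaller[k]] + smaller[k + 1 :]
        yield [[first]] + smaller


def oracle_modularity(W: np.ndarray, modules: np.ndarray) -> float:
    n = W.shape[0]
    l_w = W.sum()
    k = W.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if modules[i] == modules[j]:
                q += W[i, j] - k[i] * k[j] / l_w
    return q / l_w


def oracle_best_partition(W: np.ndarray):
    """Exhaustive max-modularity partition (n <= 6)."""
    n = W.shape[0]
    best_q, best_modules = -np.inf, None
    for part in set_partitions(list(range(n))):
        modules = np.empty(n, dtype=int)
        for m, block in enumerate(part):
            for v in block:
                modules[v] = m
        q = oracle_modularity(W, modules)
        if q > best_q:
            best_q, best_modules = q, modules
    return best_modules, best_q


def random_connected_graph(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random connected weighted graph, weights in (0, 1]."""
    while True:
        W = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.6:
                    W[i, j] = W[j, i] = rng.uniform(0.05, 1.0)
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(W[u] > 0):
                if v not in seen:
                    seen.add(int(v))
                    stack.append(int(v))
        if len(seen) == n:
            return W
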