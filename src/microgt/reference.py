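"""Naive brute-force reference implementations of the topology indexes.

Deliberately slow, definition-level code used only to validate the efficient
implementations in :mod:`microgt.metrics`: all-pairs shortest paths by
exhaustive simple-path enumeration, betweenness by direct shortest-path
counting, and maximum modularity by exhaustive search over all partitions.
Only usable on tiny graphs (<= ~8 nodes).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

__all__ = [
    "all_simple_paths",
    "shortest_path_info",
    "brute_path_length",
    "brute_global_efficiency",
    "brute_betweenness",
    "brute_modularity",
    "brute_best_partition",
    "brute_assortativity",
    "brute_degrees",
]


def _edge_lengths(a: np.ndarray, weighted: bool) -> np.ndarray:
    lengths = np.full_like(a, np.inf, dtype=float)
    mask = a > 0
    lengths[mask] = 1.0 / a[mask] if weighted else 1.0
    return lengths


def all_simple_paths(a: np.ndarray, s: int, t: int) -> list[list[int]]:
    """Every simple path from s to t by depth-first enumeration."""
    n = a.shape[0]
    paths: list[list[int]] = []

    def dfs(v: int, visited: set, path: list[int]) -> None:
        if v == t:
            paths.append(path.copy())
            return
        for w in range(n):
            if a[v, w] > 0 and w not in visited:
                visited.add(w)
                path.append(w)
                dfs(w, visited, path)
                path.pop()
                visited.remove(w)

    dfs(s, {s}, [s])
    return paths


def shortest_path_info(
    a: np.ndarray, weighted: bool, tol: float = 1e-12
) -> tuple[np.ndarray, dict]:
    """(distance matrix, {(s,t): list of shortest paths}) by enumeration."""
    n = a.shape[0]
    lengths = _edge_lengths(a, weighted)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    sp: dict = {}
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            paths = all_simple_paths(a, s, t)
            if not paths:
                sp[(s, t)] = []
                continue
            costs = [sum(lengths[p[i], p[i + 1]] for i in range(len(p) - 1)) for p in paths]
            dmin = min(costs)
            d[s, t] = dmin
            sp[(s, t)] = [p for p, c in zip(paths, costs) if c <= dmin + tol]
    return d, sp


def brute_path_length(a: np.ndarray, weighted: bool) -> tuple[float, int]:
    d, _ = shortest_path_info(a, weighted)
    n = a.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_disc = int((off & ~np.isfinite(d)).sum() // 2)
    if not finite.any():
        return float("nan"), n_disc
    return float(d[finite].mean()), n_disc


def brute_global_efficiency(a: np.ndarray, weighted: bool) -> float:
    d, _ = shortest_path_info(a, weighted)
    n = a.shape[0]
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(d)
    pos = np.isfinite(d) & (d > 0)
    inv[pos] = 1.0 / d[pos]
    return float(inv[off].mean())


def brute_betweenness(a: np.ndarray, weighted: bool) -> np.ndarray:
    """Direct definition: sum over unordered pairs of sigma_st(v)/sigma_st."""
    n = a.shape[0]
    _, sp = shortest_path_info(a, weighted)
    bc = np.zeros(n)
    for s, t in combinations(range(n), 2):
        paths = sp[(s, t)]
        if not paths:
            continue
        sigma = len(paths)
        for v in range(n):
            if v in (s, t):
                continue
            sigma_v = sum(1 for p in paths if v in p)
            bc[v] += sigma_v / sigma
    return bc


def brute_modularity(a: np.ndarray, labels: np.ndarray) -> float:
    """Q directly from its definition on the weighted adjacency."""
    two_m = a.sum()
    if two_m == 0:
        return 0.0
    k = a.sum(axis=1)
    q = 0.0
    n = a.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += (a[i, j] - k[i] * k[j] / two_m) / two_m
    return float(q)


def _partitions(items: list):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def brute_best_partition(a: np.ndarray) -> tuple[float, list]:
    """Exhaustive search for the maximum-modularity partition (<= 8 nodes)."""
    n = a.shape[0]
    if n > 8:
        raise ValueError("exhaustive partition search limited to 8 nodes")
    best_q, best_p = -np.inf, None
    for part in _partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for c, comm in enumerate(part):
            labels[comm] = c
        q = brute_modularity(a, labels)
        if q > best_q:
            best_q, best_p = q, part
    return best_q, best_p


def brute_degrees(a: np.ndarray, weighted: bool) -> np.ndarray:
    return a.sum(axis=1) if weighted else (a > 0).sum(axis=1).astype(float)


def brute_assortativity(a: np.ndarray, weighted: bool) -> float:
    """Pearson correlation on the explicitly enumerated endpoint-degree list."""
    deg = brute_degrees(a, weighted)
    xs, ys = [], []
    n = a.shape[0]
    for i in range(n):
        for j in range(n):
            if i != j and a[i, j] > 0:  # both orientations enumerated
                xs.append(deg[i])
                ys.append(deg[j])
    if not xs:
        raise ValueError("graph has no edges")
    x, y = np.array(xs), np.array(ys)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
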