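"""Independent brute-force oracles used to cross-check implementations.

The graph oracle enumerates every simple path to find shortest paths and
shortest-path counts — no graph library involved — so it can validate
the production metrics exactly on small graphs.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def _all_simple_paths(A: np.ndarray, s: int, t: int) -> list[tuple[int, ...]]:
    n = len(A)
    out = []

    def extend(path):
        v = path[-1]
        if v == t:
            out.append(tuple(path))
            return
        for u in range(n):
            if A[v, u] and u not in path:
                path.append(u)
                extend(path)
                path.pop()

    extend([s])
    return out


def shortest_paths_bf(A: np.ndarray, s: int, t: int):
    """(distance, list of shortest paths) or (inf, []) if unreachable."""
    paths = _all_simple_paths(A, s, t)
    if not paths:
        return float("inf"), []
    d = min(len(p) - 1 for p in paths)
    return d, [p for p in paths if len(p) - 1 == d]


def graph_metrics_bf(A: np.ndarray) -> dict[str, np.ndarray]:
    """Degree, clustering, nodal path length, local efficiency and
    betweenness by exhaustive path enumeration."""
    A = np.asarray(A)
    n = len(A)
    degree = A.sum(axis=1).astype(float)

    clustering = np.zeros(n)
    for v in range(n):
        neigh = np.flatnonzero(A[v])
        k = len(neigh)
        if k >= 2:
            e = sum(
                A[a, b] for i, a in enumerate(neigh) for b in neigh[i + 1 :]
            )
            clustering[v] = 2.0 * e / (k * (k - 1))

    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    n_sp = np.zeros((n, n))
    sp_lists: dict[tuple[int, int], list] = {}
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            d, paths = shortest_paths_bf(A, s, t)
            dist[s, t] = d
            n_sp[s, t] = len(paths)
            sp_lists[(s, t)] = paths

    path_length = np.full(n, np.nan)
    for v in range(n):
        finite = [dist[v, u] for u in range(n) if u != v and np.isfinite(dist[v, u])]
        if finite:
            path_length[v] = float(np.mean(finite))

    local_eff = np.zeros(n)
    for v in range(n):
        neigh = np.flatnonzero(A[v])
        k = len(neigh)
        if k >= 2:
            sub = A[np.ix_(neigh, neigh)]
            total = 0.0
            for i in range(k):
                for j in range(k):
                    if i == j:
                        continue
                    d, _ = shortest_paths_bf(sub, i, j)
                    if np.isfinite(d):
                        total += 1.0 / d
            local_eff[v] = total / (k * (k - 1))

    betweenness = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = sp_lists.get((s, t), [])
            if not paths:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                betweenness[v] += through / len(paths)

    return {
        "degree": degree,
        "clustering": clustering,
        "path_length": path_length,
        "local_efficiency": local_eff,
        "betweenness": betweenness,
    }


def global_path_length_bf(A: np.ndarray, nodes) -> tuple[float, int]:
    """Mean finite pairwise distance over ``nodes`` and the count of
    excluded (unreachable) ordered pairs."""
    total, count, excluded = 0.0, 0, 0
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            d, _ = shortest_paths_bf(np.asarray(A), s, t)
            if np.isfinite(d):
                total += d
                count += 1
            else:
                excluded += 1
    return (total / count if count else float("nan")), excluded


def pearson_bf(x, y) -> float:
    """Direct covariance / sigma formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return cov / (x.std() * y.std())
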