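"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the code paths (and, where practical, the
libraries) used by the package: plain-python Floyd-Warshall, exhaustive
simple-path enumeration for betweenness, direct rich-club enumeration, and
a hand-rolled Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def floyd_warshall(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths over 1/w edge lengths, triple loop."""
    n = weights.shape[0]
    d = [[0.0 if i == j else math.inf for j in range(n)] for i in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j and weights[i][j] > 0:
                d[i][j] = 1.0 / weights[i][j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return np.array(d)


def global_efficiency(weights: np.ndarray) -> float:
    n = weights.shape[0]
    if n < 2:
        return 0.0
    d = floyd_warshall(weights)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(d[i][j]) and d[i][j] > 0:
                total += 1.0 / d[i][j]
    return total / (n * (n - 1))


def nodal_efficiency(weights: np.ndarray) -> np.ndarray:
    n = weights.shape[0]
    d = floyd_warshall(weights)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(d[i][j]) and d[i][j] > 0:
                out[i] += 1.0 / d[i][j]
    return out / max(n - 1, 1)


def local_efficiency(weights: np.ndarray) -> np.ndarray:
    n = weights.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if weights[i][j] > 0]
        if len(nb) < 2:
            continue
        sub = weights[np.ix_(nb, nb)]
        out[i] = global_efficiency(sub)
    return out


def betweenness(weights: np.ndarray, rel_tol: float = 1e-9) -> np.ndarray:
    """Exhaustive simple-path enumeration (small graphs only).

    For each unordered pair, every simple path is enumerated, the shortest
    length identified, and each interior node credited with its fraction of
    shortest paths.
    """
    n = weights.shape[0]
    adj = {i: [j for j in range(n) if weights[i][j] > 0] for i in range(n)}
    score = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = []

        def dfs(node, visited, length):
            if node == t:
                paths.append((length, tuple(visited)))
                return
            for nxt in adj[node]:
                if nxt not in visited:
                    dfs(nxt, visited + [nxt], length + 1.0 / weights[node][nxt])

        dfs(s, [s], 0.0)
        if not paths:
            continue
        best = min(length for length, _ in paths)
        shortest = [p for length, p in paths if length <= best * (1 + rel_tol)]
        for path in shortest:
            for v in path[1:-1]:
                score[v] += 1.0 / len(shortest)
    return score


def betweenness_pathcount(weights: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
    """Betweenness from Floyd-Warshall distances and shortest-path counting.

    Independent of the package's Brandes route: sigma counts are accumulated
    over nodes ordered by distance from each source, and each interior node
    is credited with sigma_sv * sigma_vt / sigma_st.  Handles graphs up to a
    few dozen nodes.
    """
    n = weights.shape[0]
    d = floyd_warshall(weights)
    lengths = np.where(weights > 0, 1.0 / np.where(weights > 0, weights, 1), math.inf)
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        for v in np.argsort(d[s]):
            if v == s or not math.isfinite(d[s][v]):
                continue
            for u in range(n):
                if u != v and weights[u][v] > 0 and math.isfinite(d[s][u]):
                    if abs(d[s][u] + lengths[u][v] - d[s][v]) <= rtol * max(1.0, d[s][v]):
                        sigma[s, v] += sigma[s, u]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not math.isfinite(d[s][t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if abs(d[s][v] + d[v][t] - d[s][t]) <= rtol * max(1.0, d[s][t]):
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc


def rich_club(weights: np.ndarray) -> dict[int, float]:
    n = weights.shape[0]
    deg = [(weights[i] > 0).sum() for i in range(n)]
    edges = [
        (i, j, weights[i][j])
        for i in range(n)
        for j in range(i + 1, n)
        if weights[i][j] > 0
    ]
    if not edges:
        return {}
    all_w = sorted((w for _, _, w in edges), reverse=True)
    out = {}
    for k in range(int(max(deg))):
        rich_edges = [w for i, j, w in edges if deg[i] > k and deg[j] > k]
        if not rich_edges:
            continue
        out[k] = sum(rich_edges) / sum(all_w[: len(rich_edges)])
    return out


def benjamini_hochberg(p_values: list[float]) -> list[float]:
    """Step-up BH adjusted p-values."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        idx = order[rank_from_end - 1]
        value = min(prev, p_values[idx] * m / rank_from_end)
        adjusted[idx] = value
        prev = value
    return adjusted


def component_extent_scores(
    t_matrix: np.ndarray, n_steps: int, exponent_e: float, exponent_h: float
) -> np.ndarray:
    """Fine-grained TFNBS component-mode scores via scipy's connected
    components (library route independent of the package's union-find)."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    t = np.asarray(t_matrix, dtype=float)
    n = t.shape[0]
    tmax = t.max()
    scores = np.zeros_like(t)
    if tmax <= 0:
        return scores
    dh = tmax / n_steps
    iu, ju = np.triu_indices(n, k=1)
    for k in range(1, n_steps + 1):
        h = k * dh
        mask = t >= h
        adj = csr_matrix(mask)
        _, labels = connected_components(adj, directed=False)
        for i, j in zip(iu, ju):
            if not mask[i, j]:
                continue
            comp = labels[i]
            n_edges = sum(
                1
                for a, b in zip(iu, ju)
                if mask[a, b] and labels[a] == comp
            )
            scores[i, j] += n_edges**exponent_e * h**exponent_h * dh
    scores = scores + scores.T
    return scores
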