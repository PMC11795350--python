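"""Independent brute-force implementations used only to check the package.

These deliberately share no code with the implementation: distances come
from Floyd-Warshall, betweenness from exhaustive simple-path enumeration,
clustering from a triple loop, and the partial correlation from the
closed-form three-correlation identity.
"""

from itertools import permutations

import numpy as np


def floyd_warshall(dist: np.ndarray) -> np.ndarray:
    d = dist.copy().astype(float)
    n = d.shape[0]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_path_metrics(weights: np.ndarray) -> tuple[float, float]:
    """(CPL over connected pairs, global efficiency) from Floyd-Warshall."""
    n = weights.shape[0]
    with np.errstate(divide="ignore"):
        dist = np.where(weights > 0, 1.0 / weights, np.inf)
    np.fill_diagonal(dist, 0.0)
    d = floyd_warshall(dist)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    cpl = d[finite].mean()
    inv = np.zeros_like(d)
    inv[finite] = 1.0 / d[finite]
    geff = inv[off].mean()
    return float(cpl), float(geff)


def brute_betweenness(weights: np.ndarray) -> np.ndarray:
    """Normalized weighted betweenness by enumerating all simple paths."""
    n = weights.shape[0]
    with np.errstate(divide="ignore"):
        dist = np.where(weights > 0, 1.0 / weights, np.inf)
    nodes = range(n)
    bc = np.zeros(n)
    for s in nodes:
        for t in nodes:
            if s >= t:
                continue
            best = np.inf
            best_paths: list[tuple[int, ...]] = []
            for k in range(0, n - 1):
                for mid in permutations([m for m in nodes if m not in (s, t)], k):
                    path = (s, *mid, t)
                    cost = sum(dist[path[i], path[i + 1]] for i in range(len(path) - 1))
                    if not np.isfinite(cost):
                        continue
                    if cost < best - 1e-12:
                        best = cost
                        best_paths = [path]
                    elif abs(cost - best) <= 1e-12:
                        best_paths.append(path)
            if not np.isfinite(best) or not best_paths:
                continue
            for path in best_paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(best_paths)
    norm = (n - 1) * (n - 2) / 2.0
    return bc / norm


def brute_clustering(weights: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering via a triple loop (weights / global max)."""
    n = weights.shape[0]
    wmax = weights.max()
    if wmax == 0:
        return np.zeros(n)
    w = weights / wmax
    adj = weights > 0
    cc = np.zeros(n)
    for i in range(n):
        deg = int(adj[i].sum())
        if deg < 2:
            continue
        s = 0.0
        for j in range(n):
            for k in range(n):
                if j == k or not (adj[i, j] and adj[i, k] and adj[j, k]):
                    continue
                s += (w[i, j] * w[i, k] * w[j, k]) ** (1.0 / 3.0)
        cc[i] = s / (deg * (deg - 1))
    return cc


def partial_corr_identity(x, y, z) -> float:
    """r_xy|z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))."""
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    return (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
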