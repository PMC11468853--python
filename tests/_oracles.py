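"""Independent brute-force reference implementations used only by tests.

Deliberately naive: per-source queue BFS, direct triangle counting, and
shortest-path counting via adjacency-matrix powers.  These share no code
with the package's vectorised implementations.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bfs_distances(A: np.ndarray) -> np.ndarray:
    n = len(A)
    D = np.full((n, n), np.inf)
    for s in range(n):
        D[s, s] = 0
        q = deque([s])
        while q:
            u = q.popleft()
            for v in range(n):
                if A[u][v] and np.isinf(D[s, v]):
                    D[s, v] = D[s, u] + 1
                    q.append(v)
    return D


def characteristic_path_length(A: np.ndarray) -> float:
    D = bfs_distances(A)
    vals = [D[i, j] for i in range(len(A)) for j in range(len(A))
            if i != j and np.isfinite(D[i, j])]
    return float(np.mean(vals)) if vals else float("inf")


def global_efficiency(A: np.ndarray) -> float:
    D = bfs_distances(A)
    n = len(A)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]):
                total += 1.0 / D[i, j]
    return total / (n * (n - 1))


def clustering_coefficient(A: np.ndarray) -> float:
    n = len(A)
    cs = []
    for i in range(n):
        nb = [j for j in range(n) if A[i][j]]
        k = len(nb)
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(
            1 for a in range(k) for b in range(a + 1, k) if A[nb[a]][nb[b]]
        )
        cs.append(2 * links / (k * (k - 1)))
    return float(np.mean(cs))


def local_efficiency(A: np.ndarray) -> float:
    n = len(A)
    es = []
    for i in range(n):
        nb = [j for j in range(n) if A[i][j]]
        if len(nb) < 2:
            es.append(0.0)
            continue
        sub = A[np.ix_(nb, nb)]
        es.append(global_efficiency(sub))
    return float(np.mean(es))


def nodal_degree(A: np.ndarray) -> np.ndarray:
    return np.array([sum(row) for row in A], dtype=float)


def nodal_efficiency(A: np.ndarray) -> np.ndarray:
    D = bfs_distances(A)
    n = len(A)
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(
            1.0 / D[i, j] for j in range(n) if j != i and np.isfinite(D[i, j])
        ) / (n - 1)
    return out


def betweenness(A: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness via shortest-path counting by matrix powers.

    The number of shortest s-t paths equals (A^d)[s, t] with d = dist(s, t)
    (every length-d walk between nodes at distance d is a path); the count
    through v factorises as sigma(s, v) * sigma(v, t) when
    dist(s, v) + dist(v, t) = dist(s, t).
    """
    n = len(A)
    D = bfs_distances(A)
    max_d = int(np.max(D[np.isfinite(D)])) if np.isfinite(D).any() else 0
    powers = [np.eye(n, dtype=np.int64)]
    M = np.asarray(A, dtype=np.int64)
    for _ in range(max_d):
        powers.append(powers[-1] @ M)

    def sigma(s, t):
        d = D[s, t]
        return int(powers[int(d)][s, t]) if np.isfinite(d) else 0

    out = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(D[s, t]):
                continue
            total = sigma(s, t)
            for v in range(n):
                if v in (s, t):
                    continue
                if np.isfinite(D[s, v]) and np.isfinite(D[v, t]) and \
                        D[s, v] + D[v, t] == D[s, t]:
                    out[v] += sigma(s, v) * sigma(v, t) / total
    return out


def trapezoid(values, xs) -> float:
    total = 0.0
    for k in range(len(xs) - 1):
        total += 0.5 * (values[k] + values[k + 1]) * (xs[k + 1] - xs[k])
    return total
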