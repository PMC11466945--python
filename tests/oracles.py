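"""Independent brute-force oracles for the graph-metric engine.

These deliberately avoid the Brandes accumulation used in the package:
the enumeration oracle walks every simple path with DFS, and the
matrix-power oracle counts geodesics through powers of the adjacency
matrix.  Both are only feasible for the tiny pen-sized networks under
test, which is the point.
"""

from __future__ import annotations

import numpy as np


def betweenness_enumeration(
    A: np.ndarray, directed: bool, weighted: bool = False
) -> np.ndarray:
    """Betweenness by exhaustive simple-path enumeration (small n only)."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if not directed:
        A = np.maximum(A, A.T)
    with np.errstate(divide="ignore"):
        lengths = np.where(A > 0, (1.0 / A) if weighted else 1.0, np.inf)
    B = np.zeros(n)
    pairs = [
        (s, t)
        for s in range(n)
        for t in range(n)
        if s != t and (directed or s < t)
    ]
    for s, t in pairs:
        paths: list[tuple[float, list[int]]] = []

        def dfs(v: int, dist: float, path: list[int]) -> None:
            if v == t:
                paths.append((dist, list(path)))
                return
            for w in range(n):
                if np.isfinite(lengths[v, w]) and w not in path:
                    path.append(w)
                    dfs(w, dist + lengths[v, w], path)
                    path.pop()

        dfs(s, 0.0, [s])
        if not paths:
            continue
        dmin = min(d for d, _ in paths)
        geodesics = [p for d, p in paths if d == dmin]
        sigma = len(geodesics)
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in geodesics if v in p)
            B[v] += through / sigma
    return B


def betweenness_matrix_power(A: np.ndarray, directed: bool) -> np.ndarray:
    """Unweighted betweenness from geodesic counts via adjacency powers.

    sigma_st equals the (s, t) entry of A^d(s,t) (walks of minimal length
    are exactly the geodesics), and v lies on a geodesic iff
    d(s, v) + d(v, t) = d(s, t).
    """
    A = np.asarray(A) > 0
    n = A.shape[0]
    if not directed:
        A = A | A.T
    M = A.astype(np.int64)
    powers = [np.eye(n, dtype=np.int64), M]
    for _ in range(n - 1):
        powers.append(powers[-1] @ M)
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in range(n):
        for t in range(n):
            if s == t:
                dist[s, t] = 0
                sigma[s, t] = 1
                continue
            for k in range(1, n + 1):
                if powers[k][s, t] > 0:
                    dist[s, t] = k
                    sigma[s, t] = powers[k][s, t]
                    break
    B = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t or not np.isfinite(dist[s, t]):
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    B[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return B if directed else B / 2.0


def density_bruteforce(A: np.ndarray, directed: bool) -> float:
    """Edge density by explicit dyad enumeration."""
    A = np.asarray(A)
    n = A.shape[0]
    if directed:
        arcs = sum(
            1 for i in range(n) for j in range(n) if i != j and A[i, j] > 0
        )
        return arcs / (n * (n - 1))
    edges = sum(
        1
        for i in range(n)
        for j in range(i + 1, n)
        if A[i, j] > 0 or A[j, i] > 0
    )
    return edges / (n * (n - 1) / 2)


def freeman_centralization(values: np.ndarray, d_max: float) -> float:
    """Direct evaluation of the Freeman index."""
    values = np.asarray(values, dtype=float)
    return float(np.sum(values.max() - values) / d_max)
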