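"""Independent brute-force oracles for graph attributes and integrals.

Deliberately naive: matrix powers for triangle counting, scipy csgraph
Floyd-Warshall for distances, exhaustive geodesic enumeration for
betweenness, union-find for components.  None of these share code with the
package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.sparse.csgraph import floyd_warshall


def clustering_oracle(adj: np.ndarray) -> np.ndarray:
    """C_i = triangles_i / C(k_i, 2) via the diagonal of A^3."""
    A = np.asarray(adj, dtype=float)
    k = A.sum(axis=1)
    tri = np.diag(A @ A @ A) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return c


def distances_oracle(adj: np.ndarray) -> np.ndarray:
    return floyd_warshall(np.asarray(adj, dtype=float), unweighted=True)


def path_length_oracle(adj: np.ndarray) -> float:
    d = distances_oracle(adj)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    return float(d[finite].mean())


def global_efficiency_oracle(adj: np.ndarray) -> float:
    d = distances_oracle(adj)
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(d)
    finite = np.isfinite(d) & off
    inv[finite] = 1.0 / d[finite]
    return float(inv[off].sum() / (n * (n - 1)))


def local_efficiency_oracle(adj: np.ndarray) -> float:
    A = np.asarray(adj)
    n = A.shape[0]
    total = 0.0
    for v in range(n):
        nbrs = np.flatnonzero(A[v])
        if nbrs.size < 2:
            continue
        total += global_efficiency_oracle(A[np.ix_(nbrs, nbrs)])
    return total / n if n else 0.0


def betweenness_oracle(adj: np.ndarray) -> np.ndarray:
    """Exhaustive geodesic enumeration; fractional credit over ties.

    For every unordered pair (s, t) all shortest paths are enumerated by
    depth-first search constrained to the geodesic distance.
    """
    A = np.asarray(adj)
    n = A.shape[0]
    d = distances_oracle(A)
    B = np.zeros(n)

    def all_geodesics(s: int, t: int) -> list[list[int]]:
        target = d[s, t]
        paths = []

        def extend(path: list[int]) -> None:
            u = path[-1]
            if u == t:
                paths.append(path)
                return
            for w in np.flatnonzero(A[u]):
                # stay on a geodesic: one step forward must shorten the rest
                if d[s, w] == len(path) and d[w, t] == target - len(path):
                    extend(path + [int(w)])

        extend([s])
        return paths

    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(d[s, t]) or d[s, t] < 2:
                continue
            paths = all_geodesics(s, t)
            for p in paths:
                for v in p[1:-1]:
                    B[v] += 1.0 / len(paths)
    return B


def largest_component_oracle(adj: np.ndarray) -> int:
    """Union-find size of the largest connected component."""
    A = np.asarray(adj)
    n = A.shape[0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if A[i, j]:
                parent[find(i)] = find(j)
    sizes: dict[int, int] = {}
    for i in range(n):
        r = find(i)
        sizes[r] = sizes.get(r, 0) + 1
    return max(sizes.values())


def trapezoid_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Explicit trapezoid-by-trapezoid sum."""
    total = 0.0
    for k in range(len(x) - 1):
        total += 0.5 * (y[k] + y[k + 1]) * (x[k + 1] - x[k])
    return total


def all_labeled_graphs(n: int):
    """Yield adjacency matrices of every labeled simple graph on n nodes."""
    pairs = list(itertools.combinations(range(n), 2))
    for bits in itertools.product((0, 1), repeat=len(pairs)):
        adj = np.zeros((n, n), dtype=int)
        for (i, j), b in zip(pairs, bits):
            if b:
                adj[i, j] = adj[j, i] = 1
        yield adj


def random_adjacency(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    adj = (rng.random((n, n)) < p).astype(int)
    adj = np.triu(adj, 1)
    return adj + adj.T
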