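"""Binary-graph attributes and degree-preserving null models.

Metrics follow the standard unweighted, undirected conventions: clustering
index as the mean nodal transitivity (nodes of degree < 2 contribute 0),
characteristic path length as the mean geodesic over connected ordered
pairs, global efficiency as the mean inverse geodesic (0 for disconnected
pairs), local efficiency as the mean global efficiency of each node's
neighbor-induced subgraph, and betweenness with fractional credit over
equally short paths (Brandes).  Small-worldness sigma is measured against
an ensemble of Maslov-Sneppen rewired graphs that preserve the degree
sequence exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectivity import BinaryGraph


class DegenerateMetricError(ValueError):
    """A metric is undefined on this graph (e.g. mean betweenness zero)."""


def _as_graph(g) -> nx.Graph:
    if isinstance(g, BinaryGraph):
        return g.to_networkx()
    if isinstance(g, nx.Graph):
        return g
    arr = np.asarray(g)
    G = nx.Graph()
    G.add_nodes_from(range(arr.shape[0]))
    iu, ju = np.nonzero(np.triu(arr, k=1))
    G.add_edges_from(zip(iu.tolist(), ju.tolist()))
    return G


def clustering(g) -> tuple[np.ndarray, float]:
    """Nodal clustering indices and their mean over all nodes."""
    G = _as_graph(g)
    d = nx.clustering(G)
    c_i = np.array([d[v] for v in sorted(G.nodes)])
    return c_i, float(c_i.mean())


def distance_matrix(g) -> np.ndarray:
    """Geodesic (hop) distances; ``inf`` marks disconnected pairs."""
    G = _as_graph(g)
    n = G.number_of_nodes()
    pos = {v: i for i, v in enumerate(sorted(G.nodes))}
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for src, lengths in nx.all_pairs_shortest_path_length(G):
        for dst, dist in lengths.items():
            d[pos[src], pos[dst]] = dist
    return d


def path_length(g, strict: bool = False) -> tuple[float, np.ndarray]:
    """Characteristic path length and the geodesic matrix.

    By default L averages over connected ordered pairs only; in ``strict``
    mode a disconnected graph raises instead.
    """
    d = distance_matrix(g)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise DegenerateMetricError("path length undefined: graph has no edges")
    if strict and finite.sum() != off.sum():
        raise DegenerateMetricError("graph is disconnected (strict mode)")
    return float(d[finite].mean()), d


def global_efficiency(g) -> float:
    """Mean inverse geodesic over ordered pairs; 1/inf = 0 when disconnected."""
    d = distance_matrix(g)
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d == 0, np.inf, d), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def local_efficiency(g) -> float:
    """Mean over nodes of the global efficiency of the neighbor subgraph."""
    G = _as_graph(g)
    n = G.number_of_nodes()
    if n == 0:
        return 0.0
    total = 0.0
    for v in G.nodes:
        nbrs = list(G.neighbors(v))
        if len(nbrs) < 2:
            continue
        total += global_efficiency(G.subgraph(nbrs))
    return total / n


def betweenness(g) -> np.ndarray:
    """Raw betweenness B_i: shortest paths through i, fractional over ties.

    Unordered pair convention: each (s, t) pair contributes once.
    """
    G = _as_graph(g)
    b = nx.betweenness_centrality(G, normalized=False)
    return np.array([b[v] for v in sorted(G.nodes)])


def normalized_betweenness(g) -> np.ndarray:
    """NBC: b_i = B_i / <B> with <B> the network mean betweenness."""
    B = betweenness(g)
    mean = B.mean()
    if mean == 0:
        raise DegenerateMetricError(
            "mean betweenness is zero; normalized betweenness undefined"
        )
    return B / mean


def largest_component(g) -> tuple[list[int], int]:
    """Node set and size of the largest component (ties: smallest min index)."""
    G = _as_graph(g)
    comps = [sorted(c) for c in nx.connected_components(G)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    best = comps[0]
    return best, len(best)


def rewire_null(g, n_iter_per_edge: int = 10, seed: int | np.random.Generator = 0) -> nx.Graph:
    """Degree-preserving randomization by repeated double-edge swaps.

    Attempts ``n_iter_per_edge * K`` swaps of edge pairs (a,b),(c,d) ->
    (a,d),(c,b); proposals creating self-loops or duplicate edges are
    skipped, so the degree sequence is conserved exactly on every draw.
    """
    G = _as_graph(g).copy()
    K = G.number_of_edges()
    if K < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = [tuple(e) for e in G.edges()]
    adj = {v: set(G.neighbors(v)) for v in G.nodes}
    attempts = n_iter_per_edge * K
    pick = rng.integers(0, K, size=(attempts, 2))
    flips = rng.integers(0, 2, size=attempts)
    for t in range(attempts):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flips[t]:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        if d in adj[a] or b in adj[c]:
            continue
        adj[a].discard(b); adj[b].discard(a)
        adj[c].discard(d); adj[d].discard(c)
        adj[a].add(d); adj[d].add(a)
        adj[c].add(b); adj[b].add(c)
        edges[e1] = (a, d)
        edges[e2] = (c, b)
    H = nx.Graph()
    H.add_nodes_from(G.nodes)
    H.add_edges_from(edges)
    return H


@dataclass(frozen=True)
class SmallWorldResult:
    c_real: float
    l_real: float
    c_rand: float  # ensemble mean
    l_rand: float  # ensemble mean
    gamma: float
    lam: float
    sigma: float
    n_null: int


def small_world_sigma(
    g,
    n_null: int = 100,
    n_iter_per_edge: int = 10,
    seed: int | np.random.Generator = 0,
) -> SmallWorldResult:
    """Small-worldness sigma = (C/C_rand) / (L/L_rand) against rewired nulls.

    Computed on the largest component when the graph is fragmented, so L is
    defined on the same node set in the real and null graphs.
    """
    G = _as_graph(g)
    nodes, size = largest_component(G)
    if size < G.number_of_nodes():
        G = G.subgraph(nodes).copy()
    _, c_real = clustering(G)
    l_real, _ = path_length(G)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cs, ls = [], []
    for _ in range(n_null):
        H = rewire_null(G, n_iter_per_edge=n_iter_per_edge, seed=rng)
        _, c = clustering(H)
        l, _ = path_length(H)
        cs.append(c)
        ls.append(l)
    c_rand = float(np.mean(cs))
    l_rand = float(np.mean(ls))
    if c_rand == 0 or l_rand == 0:
        raise DegenerateMetricError("null ensemble mean C or L is zero; sigma undefined")
    gamma = c_real / c_rand
    lam = l_real / l_rand
    return SmallWorldResult(
        c_real=c_real,
        l_real=l_real,
        c_rand=c_rand,
        l_rand=l_rand,
        gamma=gamma,
        lam=lam,
        sigma=gamma / lam,
        n_null=n_null,
    )


def compute_metric(g, metric: str, strict: bool = False, **sigma_kwargs) -> float:
    """Evaluate a named global attribute on a binary graph.

    ``metric`` is one of ``C`` (clustering index), ``L`` (characteristic
    path length), ``Eglob``, ``Eloc``, or ``sigma``.
    """
    if metric == "C":
        return clustering(g)[1]
    if metric == "L":
        return path_length(g, strict=strict)[0]
    if metric == "Eglob":
        return global_efficiency(g)
    if metric == "Eloc":
        return local_efficiency(g)
    if metric == "sigma":
        return small_world_sigma(g, **sigma_kwargs).sigma
    raise ValueError(f"unknown metric {metric!r}; expected C, L, Eglob, Eloc or sigma")
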