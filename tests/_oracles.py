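"""Brute-force reference implementations for the six network indices.

These are deliberately naive and independent of the package (and of
networkx): explicit Dijkstra with a binary heap, exhaustive simple-path
enumeration for betweenness, BFS for hop eccentricity, a dense
non-symmetric eigensolver for eigenvector centrality and an explicit
PageRank power iteration.  They exist only to cross-check
``leafnetmap.network_properties.compute_indices``.
"""

from __future__ import annotations

import heapq
import itertools

import numpy as np


def _symmetrized(graph) -> tuple[list, dict]:
    """(nodes, adj) with adj[u][v] = max |weight| over arcs between u, v;
    zero-weight edges dropped (mirrors the documented index definitions)."""
    nodes = list(graph.nodes())
    adj: dict = {u: {} for u in nodes}
    for u, v, attrs in graph.edges(data=True):
        w = abs(attrs.get("weight", 1.0))
        if w <= 0:
            continue
        w = max(w, adj[u].get(v, 0.0))
        adj[u][v] = w
        adj[v][u] = w
    return nodes, adj


def dijkstra_lengths(adj: dict, src) -> dict:
    """Shortest-path lengths from src under edge length 1/weight."""
    dist = {src: 0.0}
    heap = [(0.0, id(src), src)]
    done = set()
    while heap:
        d, _, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v, w in adj[u].items():
            nd = d + 1.0 / w
            if v not in dist or nd < dist[v]:
                dist[v] = nd
                heapq.heappush(heap, (nd, id(v), v))
    return dist


def connectivity(graph) -> float:
    n = graph.number_of_nodes()
    return 2.0 * graph.number_of_edges() / n if n else 0.0


def closeness_mean(graph) -> float:
    nodes, adj = _symmetrized(graph)
    vals = []
    for u in nodes:
        dist = dijkstra_lengths(adj, u)
        others = [d for v, d in dist.items() if v != u]
        vals.append(len(others) / sum(others) if others else 0.0)
    return float(np.mean(vals))


def eccentricity_mean(graph) -> float:
    nodes, adj = _symmetrized(graph)
    vals = []
    for u in nodes:
        hops = {u: 0}
        frontier = [u]
        while frontier:
            nxt = []
            for a in frontier:
                for b in adj[a]:
                    if b not in hops:
                        hops[b] = hops[a] + 1
                        nxt.append(b)
            frontier = nxt
        vals.append(max(hops.values()))
    return float(np.mean(vals))


def betweenness_mean(graph) -> float:
    """Normalized betweenness by exhaustive simple-path enumeration."""
    nodes, adj = _symmetrized(graph)
    n = len(nodes)
    if n < 3:
        return 0.0
    bt = {u: 0.0 for u in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths: list[tuple[float, tuple]] = []
        stack = [(s, (s,), 0.0)]
        while stack:
            u, path, length = stack.pop()
            if u == t:
                paths.append((length, path))
                continue
            for v, w in adj[u].items():
                if v in path:
                    continue
                stack.append((v, path + (v,), length + 1.0 / w))
        if not paths:
            continue
        best = min(l for l, _ in paths)
        shortest = [p for l, p in paths if l <= best * (1 + 1e-12) + 1e-12]
        sigma = len(shortest)
        for p in shortest:
            for v in p[1:-1]:
                bt[v] += 1.0 / sigma
    scale = (n - 1) * (n - 2) / 2.0
    return float(np.mean([b / scale for b in bt.values()]))


def eigenvector_mean(graph) -> float:
    """Leading eigenvector (dense, non-symmetric LAPACK path), abs,
    L2-normalized, averaged."""
    nodes, adj = _symmetrized(graph)
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    W = np.zeros((n, n))
    for u, nbrs in adj.items():
        for v, w in nbrs.items():
            W[idx[u], idx[v]] = w
    evals, evecs = np.linalg.eig(W)
    lead = int(np.argmax(np.real(evals)))
    vec = np.abs(np.real(evecs[:, lead]))
    norm = np.linalg.norm(vec)
    return float((vec / norm).mean()) if norm > 0 else 0.0


def pagerank_mean(graph, alpha: float = 0.85) -> float:
    """Explicit power iteration replicating the standard PageRank model:
    right-stochastic by out-weight, dangling mass spread uniformly,
    uniform teleport."""
    if graph.is_directed():
        nodes = list(graph.nodes())
        out = {u: [] for u in nodes}
        for u, v, attrs in graph.edges(data=True):
            w = abs(attrs.get("weight", 1.0))
            out[u].append((v, w))
    else:
        nodes, adj = _symmetrized(graph)
        out = {u: list(nbrs.items()) for u, nbrs in adj.items()}
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    x = np.full(n, 1.0 / n)
    outsum = {u: sum(w for _, w in nbrs) for u, nbrs in out.items()}
    dangling = [u for u in nodes if outsum[u] <= 0]
    for _ in range(1_000_000):
        new = np.full(n, (1 - alpha) / n)
        dmass = sum(x[idx[u]] for u in dangling)
        new += alpha * dmass / n
        for u in nodes:
            if outsum[u] <= 0:
                continue
            xu = x[idx[u]]
            for v, w in out[u]:
                new[idx[v]] += alpha * xu * w / outsum[u]
        if np.abs(new - x).sum() < 1e-15:
            x = new
            break
        x = new
    return float(x.mean())


def all_indices(graph) -> dict:
    return {
        "Con": connectivity(graph),
        "C": closeness_mean(graph),
        "B": betweenness_mean(graph),
        "E": eccentricity_mean(graph),
        "G": eigenvector_mean(graph),
        "P": pagerank_mean(graph),
    }


def random_graph(rng: np.random.Generator, directed: bool = False):
    """A random weighted graph with 3-8 nodes (possibly disconnected)."""
    import networkx as nx

    n = int(rng.integers(3, 9))
    p = float(rng.uniform(0.2, 0.6))
    g = nx.DiGraph() if directed else nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    pairs = list(itertools.permutations(range(n), 2)) if directed else (
        list(itertools.combinations(range(n), 2)))
    for u, v in pairs:
        if rng.random() < p:
            w = float(rng.uniform(0.1, 2.0)) * (1 if rng.random() < 0.7 else -1)
            g.add_edge(f"n{u}", f"n{v}", weight=w)
    if g.number_of_edges() == 0:
        g.add_edge("n0", "n1", weight=float(rng.uniform(0.1, 2.0)))
    return g


def exact_correlated_triple(r_gz: float, r_gy: float, r_yz: float,
                            n: int = 120, seed: int = 0):
    """Vectors (g, y, z) whose sample Pearson correlations equal the given
    values to machine precision (built from an orthonormal, mean-zero basis)."""
    rng = np.random.default_rng(seed)
    M = rng.standard_normal((n, 3))
    M -= M.mean(axis=0)
    Q, _ = np.linalg.qr(M)
    Q -= Q.mean(axis=0)
    Q, _ = np.linalg.qr(Q)
    e1, e2, e3 = Q.T
    g = e1
    b_y = np.sqrt(1.0 - r_gy**2)
    y = r_gy * e1 + b_y * e2
    a = r_gz
    b = (r_yz - r_gy * a) / b_y
    c = np.sqrt(max(1.0 - a**2 - b**2, 0.0))
    z = a * e1 + b * e2 + c * e3
    return g, y, z
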