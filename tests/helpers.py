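"""Shared test utilities: hand-built grids and independent brute-force oracles."""

import itertools

import numpy as np

from grnscape.landscape import LandscapeGrid


def make_grid(F, gene_names=None):
    """LandscapeGrid from a hand-set non-negative F array (cubic shape)."""
    F = np.asarray(F, dtype=float)
    d = F.shape[0]
    assert all(s == d for s in F.shape)
    n = F.ndim
    shift = max(0.0, -float(F.min()))
    return LandscapeGrid(
        d=d,
        n_genes=n,
        coordinates=(np.arange(d) + 0.5) / d,
        F=F + shift,
        shift=shift,
        gene_names=tuple(gene_names or (f"g{i}" for i in range(n))),
        meta={},
    )


def brute_force_sccs(n, edges):
    """SCC partition by Warshall transitive closure (O(n^3))."""
    reach = np.eye(n, dtype=bool)
    for u, v in edges:
        reach[u, v] = True
    for k in range(n):
        reach |= reach[:, k : k + 1] & reach[k : k + 1, :]
    mutual = reach & reach.T
    comp = [-1] * n
    c = 0
    for v in range(n):
        if comp[v] == -1:
            for u in range(n):
                if mutual[v, u]:
                    comp[u] = c
            c += 1
    return comp


def enumerate_shortest(graph, src, tgt, weight_mode):
    """Minimal total weight over all simple paths (DFS enumeration).

    ``graph`` is a LandscapeGraph; weights are |dF| (abs) or the ascent
    max(0, dF) (uphill), on the undirected adjacency.
    """
    adj = {}
    for t, h in zip(graph.tails.tolist(), graph.heads.tolist()):
        adj.setdefault(t, []).append(h)
        adj.setdefault(h, []).append(t)

    def w(u, v):
        if weight_mode == "abs":
            return abs(graph.F[u] - graph.F[v])
        return max(0.0, graph.F[v] - graph.F[u])

    best = [np.inf]

    def dfs(u, seen, acc):
        if acc >= best[0]:
            return
        if u == tgt:
            best[0] = acc
            return
        for v in adj.get(u, ()):
            if v not in seen:
                dfs(v, seen | {v}, acc + w(u, v))

    dfs(src, {src}, 0.0)
    return best[0]


def random_digraph(rng, max_n=12):
    """A small random directed graph (n, edge list) for oracle tests."""
    n = int(rng.integers(2, max_n + 1))
    p = rng.uniform(0.1, 0.5)
    edges = [
        (u, v)
        for u, v in itertools.product(range(n), repeat=2)
        if u != v and rng.random() < p
    ]
    return n, edges
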