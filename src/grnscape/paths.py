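"""Shortest paths between attractors: commitment and reprogramming routes.

Attractors are sinks of the descending free-energy graph, so no directed
route leaves them; paths are therefore computed on the *undirected*
adjacency with non-negative weights derived from the free-energy change
across each edge.  Two defensible weight readings are provided:

``abs`` (default)
    w(u, v) = |F(u) - F(v)| on both directions; the path length is the
    total variation of F along the route, symmetric in the endpoints.
``uphill``
    w(u -> v) = max(0, F(v) - F(u)); only climbs cost, so the length is
    the total ascent, capturing jump-over-the-barrier semantics.  Forward
    and reverse lengths then differ exactly by F(target) - F(source).

Dijkstra's algorithm (non-negative weights) returns the minimal route; the
barrier height is max(F along the path) minus F at the start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .landscape import AttractorSet, LandscapeGraph, LandscapeGrid

__all__ = [
    "WEIGHT_MODES",
    "PathResult",
    "shortest_path",
    "path_profile",
    "all_pairs_attractor_paths",
]

WEIGHT_MODES = ("abs", "uphill")


@dataclass(frozen=True)
class PathResult:
    """One route between two attractors over the landscape grid."""

    cells: tuple  # index tuples, source attractor first
    states: np.ndarray  # (steps, N) cell-centre expression values
    F: np.ndarray  # free energy per step
    total_weight: float
    barrier: float
    weight_mode: str
    source: int
    target: int
    gene_names: tuple = ()

    def __post_init__(self):
        if self.total_weight < 0 or self.barrier < 0:
            raise ValueError("path length and barrier height are non-negative")
        for a, b in zip(self.cells, self.cells[1:]):
            diff = np.abs(np.subtract(a, b))
            if diff.sum() != 1:
                raise ValueError(f"cells {a} and {b} are not grid-adjacent")

    def __len__(self) -> int:
        return len(self.cells)


def _weight_matrix(graph: LandscapeGraph, weight_mode: str):
    if weight_mode not in WEIGHT_MODES:
        raise ValueError(f"unknown weight mode {weight_mode!r}; choose from {WEIGHT_MODES}")
    drop = graph.F[graph.tails] - graph.F[graph.heads]  # >= 0 by orientation
    if np.any(drop < 0):
        raise AssertionError("graph orientation violated: negative downhill drop")
    rows = np.concatenate([graph.tails, graph.heads])
    cols = np.concatenate([graph.heads, graph.tails])
    if weight_mode == "abs":
        data = np.concatenate([drop, drop])
    else:  # uphill: descending direction free, ascending costs the rise
        data = np.concatenate([np.zeros_like(drop), drop])
    # Explicit zeros are stored entries and therefore remain edges.
    return coo_matrix((data, (rows, cols)), shape=(graph.n_vertices,) * 2).tocsr()


def shortest_path(
    graph: LandscapeGraph,
    grid: LandscapeGrid,
    attractors: AttractorSet,
    source: int,
    target: int,
    weight_mode: str = "abs",
) -> PathResult:
    """Dijkstra route between two attractor representative cells."""
    n_attr = len(attractors)
    for name, idx in (("source", source), ("target", target)):
        if not 0 <= idx < n_attr:
            raise KeyError(f"{name} attractor id {idx} out of range (have {n_attr})")
    if source == target:
        raise ValueError("source and target attractors must differ")
    mat = _weight_matrix(graph, weight_mode)
    src = grid.flat_index(attractors[source].cell)
    tgt = grid.flat_index(attractors[target].cell)
    dist, pred = dijkstra(mat, directed=True, indices=src, return_predecessors=True)
    if np.isinf(dist[tgt]):
        raise AssertionError("target attractor unreachable on a connected grid")
    flat_path = [tgt]
    while flat_path[-1] != src:
        flat_path.append(int(pred[flat_path[-1]]))
    flat_path.reverse()
    cells = tuple(grid.cell_of(f) for f in flat_path)
    states = np.array([grid.state_of(c) for c in cells])
    Fvals = graph.F[np.asarray(flat_path)]
    return PathResult(
        cells=cells,
        states=states,
        F=Fvals,
        total_weight=float(dist[tgt]),
        barrier=float(Fvals.max() - Fvals[0]),
        weight_mode=weight_mode,
        source=source,
        target=target,
        gene_names=grid.gene_names,
    )


def path_profile(path: PathResult, grid: LandscapeGrid | None = None) -> pd.DataFrame:
    """Tidy per-step table: step index, one column per gene, F."""
    names = path.gene_names or (grid.gene_names if grid is not None else ())
    if not names:
        names = tuple(f"g{i}" for i in range(path.states.shape[1]))
    df = pd.DataFrame(path.states, columns=list(names))
    df.insert(0, "step", np.arange(len(path)))
    df["F"] = path.F
    return df


def all_pairs_attractor_paths(
    graph: LandscapeGraph,
    grid: LandscapeGrid,
    attractors: AttractorSet,
    weight_mode: str = "abs",
) -> list:
    """Shortest path for every ordered attractor pair."""
    if len(attractors) < 2:
        raise ValueError(f"need at least 2 attractors for paths, found {len(attractors)}")
    out = []
    for a in range(len(attractors)):
        for b in range(len(attractors)):
            if a != b:
                out.append(shortest_path(graph, grid, attractors, a, b, weight_mode))
    return out
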