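"""Grid discretization of the free energy and its directed-graph analysis.

Expression space (0, 1)^N is discretized into ``d`` cell-centred bins per
axis (centres ``(k + 1/2)/d`` stay strictly inside the open interval, where
the mixing entropy is finite).  F is evaluated at every cell centre and
shifted additively so that min(F) >= 0.  Axis-adjacent cells are joined by
one directed edge each, oriented from the higher to the lower free energy;
exact ties point towards the lexicographically smaller index tuple, a
deterministic stand-in for breaking the tie with an arbitrarily small
perturbation.  Strongly-connected-component condensation of this graph is
acyclic, and its sinks with at least one entering edge are the attractors
(cell states); basins are assigned by shortest descending distance.

With the deterministic tie rule every cycle would need constant F along
lexicographically decreasing edges, which is impossible, so in practice all
SCCs are singletons; the condensation machinery still handles the general
case (and arbitrary digraphs, for cross-checking).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .model import GeneNetwork, NoiseModel, free_energy

__all__ = [
    "DEFAULT_RESOLUTION",
    "default_resolution",
    "LandscapeGrid",
    "LandscapeGraph",
    "Attractor",
    "AttractorSet",
    "CellBudgetError",
    "evaluate_grid",
    "build_graph",
    "tarjan_scc",
    "scc_condensation",
    "find_attractors",
    "assign_basins",
]

DEFAULT_RESOLUTION = {1: 200, 2: 50, 3: 40, 4: 25}


def default_resolution(n_genes: int) -> int:
    """Bins per axis keeping the total cell count around a few 1e5."""
    if n_genes in DEFAULT_RESOLUTION:
        return DEFAULT_RESOLUTION[n_genes]
    return max(2, int(round(4e5 ** (1.0 / n_genes))))


class CellBudgetError(ValueError):
    """Raised when d^N exceeds the configured cell budget."""


@dataclass(frozen=True)
class LandscapeGrid:
    """Free-energy values over the cell-centred N-dimensional grid."""

    d: int
    n_genes: int
    coordinates: np.ndarray  # shared per-axis cell centres, length d
    F: np.ndarray  # shape (d,) * n_genes, shifted so min >= 0
    shift: float
    gene_names: tuple = ()
    meta: dict = None

    def __post_init__(self):
        if self.d < 2:
            raise ValueError("need at least 2 bins per dimension")
        if self.F.shape != (self.d,) * self.n_genes:
            raise ValueError(f"F has shape {self.F.shape}, expected {(self.d,) * self.n_genes}")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("free-energy grid contains non-finite values")
        if self.F.min() < -1e-12:
            raise ValueError("free-energy grid must be shifted to be non-negative")

    @property
    def size(self) -> int:
        return self.F.size

    @property
    def shape(self) -> tuple:
        return (self.d,) * self.n_genes

    def state_of(self, cell) -> np.ndarray:
        """Cell-centre expression vector of one index tuple."""
        return self.coordinates[np.asarray(cell, dtype=int)]

    def flat_index(self, cell) -> int:
        return int(np.ravel_multi_index(tuple(np.asarray(cell, dtype=int)), self.shape))

    def cell_of(self, flat: int) -> tuple:
        return tuple(int(x) for x in np.unravel_index(flat, self.shape))


def evaluate_grid(
    net: GeneNetwork,
    noise: NoiseModel,
    d: int | None = None,
    cell_budget: int = 10**7,
    chunk: int = 1 << 18,
) -> LandscapeGrid:
    """Evaluate F at every cell centre; O(d^N) work, chunked for memory."""
    if d is None:
        d = default_resolution(net.n)
    d = int(d)
    if d < 2:
        raise ValueError("d must be >= 2")
    n = net.n
    size = d**n
    if size > cell_budget:
        raise CellBudgetError(
            f"grid of d={d} bins over N={n} genes has {size} cells, "
            f"exceeding the budget of {cell_budget}; lower d or raise cell_budget"
        )
    coords = (np.arange(d) + 0.5) / d
    F = np.empty(size)
    for start in range(0, size, chunk):
        stop = min(start + chunk, size)
        cells = np.unravel_index(np.arange(start, stop), (d,) * n)
        V = np.stack([coords[c] for c in cells], axis=-1)
        F[start:stop] = free_energy(net, V, noise)
    fmin = F.min()
    shift = float(-fmin) if fmin < 0 else 0.0
    F += shift
    return LandscapeGrid(
        d=d,
        n_genes=n,
        coordinates=coords,
        F=F.reshape((d,) * n),
        shift=shift,
        gene_names=net.gene_names,
        meta={"T": noise.T},
    )


@dataclass(frozen=True)
class LandscapeGraph:
    """Directed graph over grid cells, edges oriented downhill in F.

    ``tails``/``heads`` are flat cell indices with ``F[tails] >= F[heads]``
    edge-wise; each axis-adjacent pair carries exactly one edge.  The SCC
    condensation is computed lazily and cached.
    """

    shape: tuple
    F: np.ndarray  # flat, length prod(shape)
    tails: np.ndarray
    heads: np.ndarray

    @property
    def n_vertices(self) -> int:
        return self.F.size

    @property
    def n_edges(self) -> int:
        return self.tails.size

    @cached_property
    def scc(self):
        """(labels, n_components, comp_tails, comp_heads) in reverse topological order."""
        return scc_condensation(self.n_vertices, self.tails, self.heads)


def build_graph(grid: LandscapeGrid) -> LandscapeGraph:
    """Orient one edge per axis-adjacent cell pair, downhill in F.

    Exact ties are broken towards the lexicographically smaller index
    tuple.  The oriented edge count is exactly N * d^(N-1) * (d-1).
    """
    n, d = grid.n_genes, grid.d
    Fflat = grid.F.ravel()
    idx = np.arange(grid.size).reshape(grid.shape)
    tails, heads = [], []
    for axis in range(n):
        lo = np.take(idx, range(d - 1), axis=axis).ravel()  # lex-smaller neighbour
        hi = np.take(idx, range(1, d), axis=axis).ravel()
        downhill = Fflat[lo] > Fflat[hi]  # ties fall to the lex-smaller cell
        tails.append(np.where(downhill, lo, hi))
        heads.append(np.where(downhill, hi, lo))
    return LandscapeGraph(
        shape=grid.shape,
        F=Fflat,
        tails=np.concatenate(tails),
        heads=np.concatenate(heads),
    )


def scc_condensation(n_vertices: int, tails, heads):
    """SCC labelling plus acyclic condensation of an arbitrary digraph.

    Returns ``(labels, n_comp, comp_tails, comp_heads)`` with component
    labels numbered in reverse topological order of the condensation
    (sinks first), matching the emission order of Tarjan's algorithm.  The
    labelling itself is delegated to scipy's strongly-connected-components
    routine; the deterministic reverse-topological relabelling uses Kahn's
    algorithm with a smallest-label-first heap.  Raises if the condensation
    were cyclic (impossible by construction; kept as a structural assert).
    """
    tails = np.asarray(tails, dtype=np.int64)
    heads = np.asarray(heads, dtype=np.int64)
    if tails.size == 0:
        return np.arange(n_vertices), n_vertices, tails, heads
    m = coo_matrix(
        (np.ones(tails.size, dtype=np.int8), (tails, heads)),
        shape=(n_vertices, n_vertices),
    ).tocsr()
    n_comp, raw = connected_components(m, directed=True, connection="strong")
    ct, ch = raw[tails], raw[heads]
    keep = ct != ch
    if not np.any(keep):
        pairs = np.empty((0, 2), dtype=np.int64)
    else:
        pairs = np.unique(np.stack([ct[keep], ch[keep]], axis=1), axis=0)
    # Kahn topological order over the condensation, deterministic.
    indeg = np.bincount(pairs[:, 1], minlength=n_comp)
    order_src = np.argsort(pairs[:, 0], kind="stable")
    sorted_tails = pairs[order_src, 0]
    sorted_heads = pairs[order_src, 1]
    starts = np.searchsorted(sorted_tails, np.arange(n_comp + 1))
    ready = [int(c) for c in np.flatnonzero(indeg == 0)]
    heapq.heapify(ready)
    topo = np.empty(n_comp, dtype=np.int64)
    indeg = indeg.copy()
    pos = 0
    while ready:
        c = heapq.heappop(ready)
        topo[pos] = c
        pos += 1
        for h in sorted_heads[starts[c] : starts[c + 1]]:
            indeg[h] -= 1
            if indeg[h] == 0:
                heapq.heappush(ready, int(h))
    if pos != n_comp:
        raise AssertionError("condensation is cyclic — SCC labelling is inconsistent")
    # Reverse topological labels: sinks get the smallest labels.
    new_label = np.empty(n_comp, dtype=np.int64)
    new_label[topo] = n_comp - 1 - np.arange(n_comp)
    labels = new_label[raw]
    comp_tails = new_label[pairs[:, 0]]
    comp_heads = new_label[pairs[:, 1]]
    return labels, n_comp, comp_tails, comp_heads


def tarjan_scc(graph: LandscapeGraph):
    """SCC condensation of a landscape graph (see :func:`scc_condensation`)."""
    return graph.scc


@dataclass(frozen=True)
class Attractor:
    """One condensation sink: a local free-energy minimum (cell state)."""

    cell: tuple
    state: np.ndarray
    F: float
    basin_size: int | None = None


@dataclass(frozen=True)
class AttractorSet:
    """Attractors sorted by F ascending, plus basin labelling once assigned.

    ``basin_labels`` maps each flat cell index to an attractor index, with
    -1 marking unresolved ridge cells (exact distance ties); it is None
    until :func:`assign_basins` has run.
    """

    attractors: tuple
    n_ridge_cells: int | None = None
    basin_labels: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.attractors)

    def __getitem__(self, i) -> Attractor:
        return self.attractors[i]


def find_attractors(graph: LandscapeGraph, grid: LandscapeGrid) -> AttractorSet:
    """Condensation sinks with indegree >= 1, one attractor each.

    A sink SCC of more than one cell is reported through its minimum-F
    member.  Attractors are sorted by F ascending (ties by flat index).
    """
    labels, n_comp, comp_tails, comp_heads = graph.scc
    outdeg = np.bincount(comp_tails, minlength=n_comp)
    indeg = np.bincount(comp_heads, minlength=n_comp)
    sink_comps = np.flatnonzero((outdeg == 0) & (indeg >= 1))
    attractors = []
    for c in sink_comps:
        members = np.flatnonzero(labels == c)
        rep = int(members[np.lexsort((members, graph.F[members]))[0]])
        attractors.append(
            Attractor(
                cell=grid.cell_of(rep),
                state=grid.state_of(grid.cell_of(rep)),
                F=float(graph.F[rep]),
            )
        )
    attractors.sort(key=lambda a: (a.F, a.cell))
    return AttractorSet(attractors=tuple(attractors))


def assign_basins(
    graph: LandscapeGraph, grid: LandscapeGrid, attractors: AttractorSet
) -> AttractorSet:
    """Label every cell with the attractor it descends to.

    A cell from which only one attractor is reachable along directed
    (descending) edges belongs to that attractor's basin.  When several are
    reachable the cell goes to the attractor with the smaller Dijkstra
    distance along descending edges (weight F(tail) - F(head) >= 0);
    remaining exact distance ties are labelled ridge (-1).  Both rules
    collapse to a single argmin because unreachable attractors sit at
    infinite distance.
    """
    if len(attractors) == 0:
        raise ValueError("no attractors to assign basins to")
    w = graph.F[graph.tails] - graph.F[graph.heads]
    # Reverse edges so source-based Dijkstra from each attractor yields
    # cell -> attractor descent distances.  Explicit zero weights (tie
    # edges) are stored entries, hence kept as edges by csgraph.
    mat = coo_matrix(
        (w, (graph.heads, graph.tails)), shape=(graph.n_vertices, graph.n_vertices)
    ).tocsr()
    reps = [grid.flat_index(a.cell) for a in attractors.attractors]
    dist = dijkstra(mat, directed=True, indices=reps)
    best = np.min(dist, axis=0)
    if np.any(np.isinf(best)):
        raise AssertionError("a grid cell cannot descend to any attractor")
    ties = np.sum(dist == best[None, :], axis=0)
    labels = np.argmin(dist, axis=0).astype(np.int64)
    labels[ties > 1] = -1
    sizes = np.bincount(labels[labels >= 0], minlength=len(attractors))
    new_attractors = tuple(
        Attractor(a.cell, a.state, a.F, basin_size=int(sizes[i]))
        for i, a in enumerate(attractors.attractors)
    )
    return AttractorSet(
        attractors=new_attractors,
        n_ridge_cells=int(np.sum(labels == -1)),
        basin_labels=labels,
    )
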