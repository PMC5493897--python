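"""Configuration I/O and result export.

Network configs are YAML (JSON, being a YAML subset, is accepted by the
same loader) with keys ``genes``, ``W`` (row = source gene, column =
target gene), ``l``, ``T`` and optional ``metadata``.  Tabular results go
to TSV with a ``#``-prefixed header block recording tool version, seed,
network hash and the run parameters, so any output can be reproduced
exactly.  Landscape grids are exported to HDF5 (and, for one or two
genes, to long-format TSV); landscape graphs can be written to GraphML
for external inspection.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .landscape import LandscapeGraph, LandscapeGrid
from .model import GeneNetwork, NoiseModel

__all__ = [
    "ConfigError",
    "load_network",
    "save_network",
    "network_hash",
    "write_table",
    "grid_to_hdf5",
    "grid_to_tsv",
    "graph_to_graphml",
]


class ConfigError(ValueError):
    """A network config file violates the schema."""


def _require(cfg: dict, key: str, path):
    if key not in cfg:
        raise ConfigError(f"{path}: missing required key '{key}'")
    return cfg[key]


def load_network(path) -> tuple:
    """Read and validate a network config; returns (GeneNetwork, NoiseModel).

    Error messages name the offending field and, where relevant, the
    offending dimensions; the row-equals-source orientation of ``W`` is
    stated whenever a shape mismatch could stem from a transposed matrix.
    """
    path = Path(path)
    try:
        cfg = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON: {exc}")
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    genes = _require(cfg, "genes", path)
    if not isinstance(genes, list) or not genes:
        raise ConfigError(f"{path}: 'genes' must be a non-empty list of names")
    n = len(genes)
    W = _require(cfg, "W", path)
    try:
        W = np.asarray(W, dtype=float)
    except (TypeError, ValueError):
        raise ConfigError(f"{path}: 'W' must be a numeric matrix")
    if W.shape != (n, n):
        raise ConfigError(
            f"{path}: 'W' has shape {W.shape} but {n} genes were listed; "
            "W must be square with row = source gene, column = target gene"
        )
    l = _require(cfg, "l", path)
    try:
        l = np.asarray(l, dtype=float)
    except (TypeError, ValueError):
        raise ConfigError(f"{path}: 'l' must be a numeric vector")
    if l.shape != (n,):
        raise ConfigError(f"{path}: 'l' has shape {l.shape}, expected ({n},)")
    T = _require(cfg, "T", path)
    try:
        noise = NoiseModel(float(T))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: 'T' invalid: {exc}")
    metadata = cfg.get("metadata", {})
    if metadata is None:
        metadata = {}
    if not isinstance(metadata, dict):
        raise ConfigError(f"{path}: 'metadata' must be a mapping")
    try:
        net = GeneNetwork(genes, W, l, metadata=metadata)
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}")
    return net, noise


def save_network(net: GeneNetwork, noise: NoiseModel, path) -> None:
    """Write a network config; format chosen by extension (.json or YAML)."""
    path = Path(path)
    cfg = {
        "genes": list(net.gene_names),
        "W": [[float(x) for x in row] for row in net.W],
        "l": [float(x) for x in net.l],
        "T": noise.T,
        "metadata": dict(net.metadata),
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))


def network_hash(net: GeneNetwork) -> str:
    """Short content hash of a network (names, W, l), for output headers."""
    h = hashlib.sha256()
    h.update("|".join(net.gene_names).encode())
    h.update(np.ascontiguousarray(np.round(net.W, 12)).tobytes())
    h.update(np.ascontiguousarray(np.round(net.l, 12)).tobytes())
    return h.hexdigest()[:12]


def _header_lines(meta: dict) -> str:
    from . import __version__

    lines = [f"# grnscape {__version__}"]
    for key, val in meta.items():
        lines.append(f"# {key}: {val}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """TSV with a reproducibility header block (# key: value lines)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta or {}))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`, skipping header comments."""
    return pd.read_csv(path, sep="\t", comment="#")


def grid_to_hdf5(grid: LandscapeGrid, path, meta: dict | None = None) -> None:
    """Write grid F values and axis coordinates to an HDF5 file."""
    from . import __version__

    with h5py.File(path, "w") as fh:
        fh.create_dataset("F", data=grid.F)
        fh.create_dataset("coordinates", data=grid.coordinates)
        fh.attrs["d"] = grid.d
        fh.attrs["N"] = grid.n_genes
        fh.attrs["shift"] = grid.shift
        fh.attrs["gene_names"] = list(grid.gene_names)
        fh.attrs["version"] = __version__
        for key, val in (meta or {}).items():
            fh.attrs[key] = val


def grid_to_tsv(grid: LandscapeGrid, path, meta: dict | None = None) -> None:
    """Long-format TSV (bin indices, coordinates, F); one or two genes only."""
    if grid.n_genes > 2:
        raise ValueError(
            f"TSV export supported for N <= 2, this grid has N = {grid.n_genes}; use HDF5"
        )
    cells = np.indices(grid.shape).reshape(grid.n_genes, -1).T
    data = {}
    for ax, name in enumerate(grid.gene_names):
        data[f"bin_{name}"] = cells[:, ax]
    for ax, name in enumerate(grid.gene_names):
        data[name] = grid.coordinates[cells[:, ax]]
    data["F"] = grid.F.ravel()
    write_table(pd.DataFrame(data), path, meta)


def graph_to_graphml(graph: LandscapeGraph, path, max_vertices: int = 200_000) -> None:
    """Export the directed landscape graph to GraphML via networkx."""
    import networkx as nx

    if graph.n_vertices > max_vertices:
        raise ValueError(
            f"graph has {graph.n_vertices} vertices, above the GraphML cap of "
            f"{max_vertices}; export is meant for small grids"
        )
    g = nx.DiGraph()
    for v in range(graph.n_vertices):
        g.add_node(v, F=float(graph.F[v]))
    for u, w in zip(graph.tails.tolist(), graph.heads.tolist()):
        g.add_edge(u, w, dF=float(graph.F[u] - graph.F[w]))
    nx.write_graphml(g, path)
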