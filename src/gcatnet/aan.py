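"""The amino-acid network (AAN): residues as nodes, atomic proximity as edges.

Two residues are linked when any pair of their heavy atoms lies within the
distance cutoff (5 Å by default, closed comparison: ``d <= cutoff``). All
residues of the structure appear as nodes, including isolated ones, so that
a residue gaining its first neighbor in a mutant is a detectable change.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from gcatnet.structure_io import ResidueId, Structure


def build_aan(structure: Structure, cutoff: float = 5.0) -> nx.Graph:
    """Build the undirected amino-acid network of ``structure``.

    An edge ``(i, j)`` is present iff some heavy atom of residue ``i`` and
    some heavy atom of residue ``j`` are at Euclidean distance ``<= cutoff``
    (Å). Self-edges are never created. The cutoff is stored as the graph
    attribute ``"cutoff"``.

    Uses a k-d tree over all atoms; the decision per residue pair is
    identical to a brute-force all-pairs atom scan.
    """
    if len(structure) == 0:
        raise ValueError("cannot build an AAN from an empty structure")
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")

    coords = []
    owner: list[ResidueId] = []
    for res in structure:
        for atom in res.atoms:
            coords.append(atom.coords)
            owner.append(res.id)
    tree = cKDTree(np.asarray(coords))

    graph = nx.Graph(cutoff=float(cutoff))
    graph.add_nodes_from(structure.ids)
    for a, b in tree.query_pairs(r=float(cutoff)):
        i, j = owner[a], owner[b]
        if i != j:
            graph.add_edge(i, j)
    return graph


def neighborhood(aan: nx.Graph, position: ResidueId) -> set[ResidueId]:
    """The set of AAN neighbors of ``position`` (its position neighborhood)."""
    if position not in aan:
        raise KeyError(f"position {position} not in AAN")
    return set(aan.neighbors(position))


def degree(aan: nx.Graph, position: ResidueId) -> int:
    """Node degree: the number of chemical (first-shell) neighbors."""
    return len(neighborhood(aan, position))


def _plain(value):
    """Coerce attribute values to GraphML/GEXF-serializable primitives."""
    if isinstance(value, (set, frozenset, list, tuple)):
        return ",".join(sorted(str(v) for v in value))
    if isinstance(value, (bool, int, float, str)):
        return value
    return str(value)


def _stringify(graph: nx.Graph) -> nx.Graph:
    out = nx.DiGraph() if graph.is_directed() else nx.Graph()
    out.graph.update({k: _plain(v) for k, v in graph.graph.items()})
    for n, data in sorted(graph.nodes(data=True), key=lambda t: str(t[0])):
        out.add_node(str(n), **{k: _plain(v) for k, v in data.items()})
    for u, v, data in sorted(graph.edges(data=True), key=lambda t: (str(t[0]), str(t[1]))):
        out.add_edge(str(u), str(v), **{k: _plain(v) for k, v in data.items()})
    return out


def write_graphml(graph: nx.Graph, path: str | Path) -> Path:
    """Export with string node ids (Gephi-compatible)."""
    path = Path(path)
    nx.write_graphml(_stringify(graph), path)
    return path


def write_gexf(graph: nx.Graph, path: str | Path) -> Path:
    path = Path(path)
    nx.write_gexf(_stringify(graph), path)
    return path


def edge_table(graph: nx.Graph) -> pd.DataFrame:
    """Edge list as a DataFrame with ``source``/``target`` columns, sorted."""
    rows = sorted((str(u), str(v)) for u, v in graph.edges)
    return pd.DataFrame(rows, columns=["source", "target"])


def write_edge_csv(graph: nx.Graph, path: str | Path) -> Path:
    path = Path(path)
    edge_table(graph).to_csv(path, index=False)
    return path
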