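"""Shared fixtures: formatted PDB text, synthetic structures, graph oracles."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from gcatnet import build_aan, make_synthetic_structure


def pdb_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    x: float,
    y: float,
    z: float,
    occ: float = 1.0,
    altloc: str = " ",
    element: str | None = None,
    record: str = "ATOM",
    icode: str = " ",
) -> str:
    """One correctly column-aligned ATOM/HETATM record."""
    element = element if element is not None else name[0]
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:>5d} {name_field}{altloc}{resname:<3s} {chain}"
        f"{resseq:>4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def two_residue_pdb(tmp_path):
    """Minimal two-residue PDB: GLY at 4.0 Å CA-CA from ALA."""
    lines = [
        pdb_line(1, "N", "GLY", "A", 1, 0.0, -1.4, 0.0),
        pdb_line(2, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0),
        pdb_line(3, "C", "GLY", "A", 1, 1.4, 0.5, 0.0),
        pdb_line(4, "O", "GLY", "A", 1, 2.0, 1.2, 0.8, element="O"),
        pdb_line(5, "N", "ALA", "A", 2, 4.0, -1.4, 0.0),
        pdb_line(6, "CA", "ALA", "A", 2, 4.0, 0.0, 0.0),
        pdb_line(7, "C", "ALA", "A", 2, 5.4, 0.5, 0.0),
        pdb_line(8, "O", "ALA", "A", 2, 6.0, 1.2, 0.8, element="O"),
        pdb_line(9, "CB", "ALA", "A", 2, 3.5, 0.8, 1.2),
        "END",
    ]
    path = tmp_path / "two.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def walk20():
    return make_synthetic_structure(20, geometry="chain-walk", seed=11)


@pytest.fixture
def walk20_aan(walk20):
    return build_aan(walk20, cutoff=5.0)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_aan_edges(structure, cutoff: float) -> set[frozenset]:
    """All-pairs atom-distance scan: the reference AAN edge set."""
    edges = set()
    for r1, r2 in itertools.combinations(structure.residues, 2):
        d = np.linalg.norm(r1.coords[:, None, :] - r2.coords[None, :, :], axis=-1)
        if d.min() <= cutoff:
            edges.add(frozenset((r1.id, r2.id)))
    return edges


def reachability_matrix(graph: nx.DiGraph):
    """Boolean transitive closure by iterated squaring (independent of Tarjan)."""
    nodes = sorted(graph.nodes, key=str)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    reach = np.eye(n, dtype=bool)
    for u, v in graph.edges:
        reach[index[u], index[v]] = True
    while True:
        nxt = reach | (reach @ reach)
        if (nxt == reach).all():
            return nodes, reach
        reach = nxt


def scc_partition_by_reachability(graph: nx.DiGraph) -> set[frozenset]:
    nodes, reach = reachability_matrix(graph)
    mutual = reach & reach.T
    return {
        frozenset(nodes[j] for j in np.flatnonzero(mutual[i]))
        for i in range(len(nodes))
    }


def random_digraph(seed: int, n: int = 40, p: float = 0.08) -> nx.DiGraph:
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u in range(n):
        for v in range(n):
            if u != v and rng.random() < p:
                g.add_edge(u, v)
    return g
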