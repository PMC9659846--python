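"""Network measures and attribute-based sub-network analyses for GCAT graphs.

Covers strongly connected components, the directed clustering coefficient
with denominator k(k-1), bidirectional (mutual-influence) edges, induced
sub-networks on boolean residue attributes (surface-exposed, sector,
functionally sensitive position, hotspot), and the homogeneous /
heterogeneous influence-mixing classification of nodes.

Clustering convention: the neighbor set of *i* is the union of its in- and
out-neighbors (excluding *i*); the numerator counts directed edges between
those neighbors, each ordered pair at most once, so a reciprocal pair
contributes 2. Nodes with fewer than two neighbors have coefficient 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from gcatnet.structure_io import ResidueId

EXCLUSIVE_HOMOGENEOUS = "exclusive-homogeneous"
EXCLUSIVE_HETEROGENEOUS = "exclusive-heterogeneous"
COMBINED = "combined"

DEFAULT_ATTRIBUTES = ("se", "sector", "fsp", "hotspot")


@dataclass
class AnnotationTable:
    """Boolean per-residue attribute flags (SE/buried, sector, FSP, hotspot…)."""

    flags: dict[ResidueId, dict[str, bool]]

    def get(self, rid: ResidueId, attribute: str) -> bool:
        return bool(self.flags.get(rid, {}).get(attribute, False))

    def attributes(self) -> list[str]:
        names: set[str] = set()
        for f in self.flags.values():
            names.update(f)
        return sorted(names)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AnnotationTable":
        """Read a CSV with a ``residue_id`` column plus boolean flag columns.

        Accepted truthy cell values: 1/true/yes (case-insensitive); blank
        cells and 0/false/no are False.
        """
        frame = pd.read_csv(path, dtype=str).fillna("")
        if "residue_id" not in frame.columns:
            raise ValueError(f"{path}: annotation CSV needs a 'residue_id' column")
        flags: dict[ResidueId, dict[str, bool]] = {}
        truthy = {"1", "true", "yes", "y"}
        for _, row in frame.iterrows():
            rid = ResidueId.parse(row["residue_id"])
            flags[rid] = {
                col: row[col].strip().lower() in truthy
                for col in frame.columns
                if col != "residue_id"
            }
        return cls(flags)

    def to_frame(self) -> pd.DataFrame:
        cols = self.attributes()
        rows = [
            {"residue_id": str(rid), **{c: int(self.get(rid, c)) for c in cols}}
            for rid in sorted(self.flags)
        ]
        return pd.DataFrame(rows)


@dataclass
class SubnetworkReport:
    """Measures for the sub-network of nodes with ``attribute == value``.

    ``n_scc`` and ``global_cc`` are computed on the induced subgraph
    (cross-flag edges dropped). Bidirectional-edge and influence-mixing
    statistics are computed on the full graph, classifying each flagged
    node by the flags of its edge partners, as in attribute-overlay
    analyses of the whole network.
    """

    attribute: str
    value: bool
    n_nodes: int
    n_edges: int
    n_scc: int
    global_cc: float
    n_bidirectional_nodes: int
    node_influence_class: dict[ResidueId, str] = field(default_factory=dict)
    bidirectional_class: dict[ResidueId, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "attribute": self.attribute,
            "value": self.value,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_scc": self.n_scc,
            "global_cc": self.global_cc,
            "n_bidirectional_nodes": self.n_bidirectional_nodes,
            "node_influence_class": {str(k): v for k, v in sorted(self.node_influence_class.items())},
            "bidirectional_class": {str(k): v for k, v in sorted(self.bidirectional_class.items())},
        }

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path


def strongly_connected_components(graph: nx.DiGraph) -> list[set[ResidueId]]:
    """SCC partition, ordered by the smallest residue id in each component."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    components = [set(c) for c in nx.strongly_connected_components(graph)]
    return sorted(components, key=lambda c: min(c))


def clustering_coefficient(graph: nx.DiGraph, node: ResidueId) -> float:
    """Directed clustering coefficient of one node.

    With k the number of distinct (in ∪ out) neighbors of the node, the
    value is (directed edges among those neighbors) / (k·(k−1)); 0 when
    k < 2 (no triangle is possible).
    """
    if node not in graph:
        raise KeyError(f"node {node} not in graph")
    nbrs = (set(graph.predecessors(node)) | set(graph.successors(node))) - {node}
    k = len(nbrs)
    if k < 2:
        return 0.0
    realized = sum(1 for u in nbrs for v in nbrs if u != v and graph.has_edge(u, v))
    return realized / (k * (k - 1))


def global_clustering(graph: nx.DiGraph) -> float:
    """Unweighted mean of the per-node clustering coefficients."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    return sum(clustering_coefficient(graph, n) for n in graph.nodes) / graph.number_of_nodes()


def bidirectional_edges(graph: nx.DiGraph) -> set[frozenset]:
    """Unordered pairs {i, j} with both i→j and j→i present (mutual influence)."""
    return {
        frozenset((u, v))
        for u, v in graph.edges
        if u != v and graph.has_edge(v, u)
    }


def subnetwork(
    graph: nx.DiGraph, annotations: AnnotationTable, attribute: str, value: bool = True
) -> nx.DiGraph:
    """Induced subgraph on nodes whose ``attribute`` flag equals ``value``.

    Every graph node must be annotated for ``attribute`` (explicitly present
    in the table); edges with either endpoint outside the selection are
    dropped and degrees are those of the subgraph.
    """
    missing = [
        str(n) for n in graph.nodes
        if n not in annotations.flags or attribute not in annotations.flags[n]
    ]
    if missing:
        raise ValueError(f"attribute {attribute!r} missing for positions {missing}")
    keep = [n for n in graph.nodes if annotations.get(n, attribute) == value]
    sub = graph.subgraph(keep).copy()
    sub.graph.update(graph.graph)
    sub.graph["attribute"] = attribute
    sub.graph["value"] = value
    return sub


def _mixing_class(same: int, different: int) -> str | None:
    if same and different:
        return COMBINED
    if same:
        return EXCLUSIVE_HOMOGENEOUS
    if different:
        return EXCLUSIVE_HETEROGENEOUS
    return None


def influence_mixing(
    graph: nx.DiGraph, annotations: AnnotationTable, attribute: str, value: bool = True
) -> SubnetworkReport:
    """Attribute overlay analysis for nodes with ``attribute == value``.

    Per flagged node, incident edges (in or out, on the full graph) are
    split into homogeneous (partner carries the same flag value) and
    heterogeneous (partner differs): a node is *exclusive-homogeneous*,
    *exclusive-heterogeneous*, or *combined*. The same trichotomy is applied
    to each node's bidirectional partners. SCC count and global clustering
    coefficient are those of the induced sub-network.
    """
    sub = subnetwork(graph, annotations, attribute, value)
    n_scc = len(strongly_connected_components(sub)) if sub.number_of_nodes() else 0
    cc = global_clustering(sub) if sub.number_of_nodes() else 0.0

    flagged = set(sub.nodes)
    node_class: dict[ResidueId, str] = {}
    bidir_class: dict[ResidueId, str] = {}
    mutual = bidirectional_edges(graph)
    for node in sorted(flagged):
        partners = [u for u, _ in graph.in_edges(node)] + [
            v for _, v in graph.out_edges(node)
        ]
        same = sum(1 for p in partners if annotations.get(p, attribute) == value)
        diff = len(partners) - same
        cls = _mixing_class(same, diff)
        if cls is not None:
            node_class[node] = cls
        bidir_partners = [next(iter(pair - {node})) for pair in mutual if node in pair]
        same_b = sum(1 for p in bidir_partners if annotations.get(p, attribute) == value)
        diff_b = len(bidir_partners) - same_b
        cls_b = _mixing_class(same_b, diff_b)
        if cls_b is not None:
            bidir_class[node] = cls_b

    return SubnetworkReport(
        attribute=attribute,
        value=value,
        n_nodes=sub.number_of_nodes(),
        n_edges=sub.number_of_edges(),
        n_scc=n_scc,
        global_cc=cc,
        n_bidirectional_nodes=len(bidir_class),
        node_influence_class=node_class,
        bidirectional_class=bidir_class,
    )
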