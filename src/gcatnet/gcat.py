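"""The GCAT network: directed aggregation of mutational neighborhood changes.

For every mutation at position *i*, each position *j* whose AAN neighbor
set differs between the mutant and the wild type (gain, loss or swap of
neighbors) receives a directed influence edge *i → j*. Edges are aggregated
(deduplicated) over the 19 mutations of each position; self-edges are never
added; positions with no influence in either direction are excluded from
the network. Nodes are then classified into the four influence categories
G/C/A/T by comparing their in- and out-degree to the network mean degree
|E|/N (an exact rational, not a rounded report):

====  ==================  ===================
 G     k_in <= mean        k_out > mean
 C     k_in <= mean        k_out <= mean
 A     k_in > mean         k_out <= mean
 T     k_in > mean         k_out > mean
====  ==================  ===================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from gcatnet.aan import build_aan
from gcatnet.mutants import MutantSet, MutationSpec
from gcatnet.structure_io import ResidueId

CATEGORIES = ("G", "C", "A", "T")


@dataclass
class NeighborhoodDiff:
    """Positions whose AAN neighbor set changed under one mutation."""

    mutation: MutationSpec
    changed_positions: set[ResidueId]


def diff_neighborhoods(
    wt_aan: nx.Graph, mutant_aan: nx.Graph, mutation: MutationSpec
) -> NeighborhoodDiff:
    """Per-position neighbor-set comparison of a mutant AAN against the WT AAN.

    A position counts as changed on any set inequality — neighbors gained,
    lost, or swapped. The mutation site itself is included here when its own
    neighborhood changed; self-influence is discarded later, at edge
    creation, not in the diff.
    """
    if set(wt_aan.nodes) != set(mutant_aan.nodes):
        raise ValueError("wild-type and mutant AANs are over different node sets")
    changed = {
        node
        for node in wt_aan.nodes
        if set(wt_aan.neighbors(node)) != set(mutant_aan.neighbors(node))
    }
    return NeighborhoodDiff(mutation, changed)


def aggregate_influences(
    diffs: Iterable[tuple[ResidueId, Iterable[ResidueId]]],
) -> nx.DiGraph:
    """Aggregate per-mutation neighborhood changes into the GCAT digraph.

    ``diffs`` yields ``(mutation_site, changed_positions)`` pairs — or
    ``(site, changed, label)`` triples — one per mutation. For each entry,
    edges ``site -> j`` are added for every changed ``j != site`` (no
    self-edges); repeated influences across mutations of the same site are
    deduplicated. Each edge keeps a ``"provenance"`` set of the mutation
    labels that produced it. Positions that end up with no incident edge do
    not appear in the graph.
    """
    graph = nx.DiGraph()
    for entry in diffs:
        site, changed, label = entry if len(entry) == 3 else (*entry, None)
        label = str(site) if label is None else label
        for j in changed:
            if j == site:
                continue
            if graph.has_edge(site, j):
                graph[site][j]["provenance"].add(label)
            else:
                graph.add_edge(site, j, provenance={label})
    return graph


def build_gcat(
    wt_aan: nx.Graph,
    mutant_set: MutantSet,
    cutoff: float | None = None,
) -> nx.DiGraph:
    """Build the GCAT network from a wild-type AAN and a set of mutants.

    For every mutant, the mutant AAN is built at ``cutoff`` (defaulting to
    the wild-type AAN's cutoff), its neighborhoods are diffed against the
    wild type, and influence edges from the mutation site are aggregated.
    Partial mutant sets are allowed (a warning is emitted); per-position
    coverage is available from ``mutant_set.coverage()``.
    """
    if len(mutant_set.entries) == 0:
        raise ValueError("empty mutant set")
    if cutoff is None:
        cutoff = wt_aan.graph.get("cutoff", 5.0)

    n_expected = 19 * len(mutant_set.wildtype)
    if len(mutant_set.entries) < n_expected:
        warnings.warn(
            f"partial mutant set: {len(mutant_set.entries)}/{n_expected} mutants",
            stacklevel=2,
        )

    def diff_stream():
        for spec, mutant in mutant_set.entries.items():
            mutant_aan = build_aan(mutant, cutoff=cutoff)
            diff = diff_neighborhoods(wt_aan, mutant_aan, spec)
            yield spec.position, diff.changed_positions, str(spec)

    graph = aggregate_influences(diff_stream())
    graph.graph["cutoff"] = float(cutoff)
    graph.graph["provider"] = mutant_set.provider
    return graph


def mean_degree(graph: nx.DiGraph) -> float:
    """|E|/N — equal to both the mean in-degree and the mean out-degree."""
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("empty GCAT graph")
    return graph.number_of_edges() / n


def classify_gcat(graph: nx.DiGraph) -> dict[ResidueId, str]:
    """Assign each node its influence category (G, C, A or T).

    Comparisons use the exact mean degree |E|/N; a node sitting exactly on
    the mean in both degrees falls in C (the ``<=`` quadrant).
    """
    mean = mean_degree(graph)
    labels: dict[ResidueId, str] = {}
    for node in graph.nodes:
        high_in = graph.in_degree(node) > mean
        high_out = graph.out_degree(node) > mean
        if high_out:
            labels[node] = "T" if high_in else "G"
        else:
            labels[node] = "A" if high_in else "C"
    return labels


def category_counts(labels: Mapping[ResidueId, str]) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    for lab in labels.values():
        counts[lab] += 1
    return counts


def excluded_positions(wt_aan: nx.Graph, gcat: nx.DiGraph) -> list[ResidueId]:
    """Positions of the structure absent from the GCAT network.

    These neither influence any position upon their own mutations nor have
    their neighborhood changed by mutations elsewhere — complete mutational
    independence from the rest of the system.
    """
    return sorted(set(wt_aan.nodes) - set(gcat.nodes))
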