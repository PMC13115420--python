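"""miRNA-target interaction network: grouping, degrees, hubs, circular layout.

The network is restricted to the targets of two miRNAs that fall inside the
shared disease gene list.  Nodes are grouped by regulating miRNA
(A-only / B-only / shared targets); edges come from a scored interactome
and are kept when both endpoints are present and the confidence reaches a
STRING-style threshold.  Degree (the number of connections) is the sole
centrality; the top-degree genes per group are the hubs, placed clockwise
on a unit circle in decreasing-degree order.

Cross-group edges count toward degrees by default (connectivity is assessed
before between-group interactions are hidden in the layout export); set
``cross_group_in_degrees=False`` to drop them from degrees as well.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger("mirshare.network")

GROUP_A_ONLY = "A_only_targets"
GROUP_B_ONLY = "B_only_targets"
GROUP_SHARED = "shared_targets"
GROUPS = (GROUP_A_ONLY, GROUP_SHARED, GROUP_B_ONLY)


@dataclass
class InteractionNetwork:
    """Grouped gene nodes with scored undirected edges."""

    graph: nx.Graph
    groups: dict[str, str]  # gene -> group

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["confidence"]) for u, v, d in self.graph.edges(data=True)]

    def group_members(self, group: str) -> list[str]:
        return sorted(g for g, grp in self.groups.items() if grp == group)


@dataclass
class HubSelection:
    """Top-degree genes of one group with their circular layout."""

    group: str
    hubs: list[str]
    degrees: dict[str, int]
    layout: dict[str, tuple[float, float]] = field(default_factory=dict)


def build_network(
    edges: pd.DataFrame,
    targets_A: Iterable[str],
    targets_B: Iterable[str],
    shared_gene_list: Iterable[str],
    min_confidence: float = 0.4,
) -> InteractionNetwork:
    """Filter the interactome to shared-gene targets of the two miRNAs.

    Node set: (targets_A ∪ targets_B) ∩ shared_gene_list.  Edges are kept
    when both endpoints are nodes and confidence >= ``min_confidence``;
    self-loops are dropped and duplicate unordered pairs collapse to the
    maximum confidence.
    """
    targets_A, targets_B = set(targets_A), set(targets_B)
    shared_gene_list = set(shared_gene_list)
    nodes = (targets_A | targets_B) & shared_gene_list
    if not nodes:
        raise ValueError("empty node set: no targets fall in the shared gene list")
    bad = edges[(edges["confidence"] < 0) | (edges["confidence"] > 1)]
    if len(bad):
        raise ValueError("edge confidences must lie in [0, 1]")
    groups = {}
    for g in nodes:
        in_a, in_b = g in targets_A, g in targets_B
        groups[g] = GROUP_SHARED if (in_a and in_b) else (GROUP_A_ONLY if in_a else GROUP_B_ONLY)
    graph = nx.Graph()
    graph.add_nodes_from(sorted(nodes))
    kept = edges[
        edges["geneA"].isin(nodes)
        & edges["geneB"].isin(nodes)
        & (edges["confidence"] >= min_confidence)
        & (edges["geneA"] != edges["geneB"])
    ]
    for row in kept.itertuples(index=False):
        u, v, c = row.geneA, row.geneB, float(row.confidence)
        if graph.has_edge(u, v):
            graph[u][v]["confidence"] = max(graph[u][v]["confidence"], c)
        else:
            graph.add_edge(u, v, confidence=c)
    logger.info(
        "build_network: %d nodes, %d/%d edges kept at confidence >= %s",
        graph.number_of_nodes(), graph.number_of_edges(), len(edges), min_confidence,
    )
    return InteractionNetwork(graph=graph, groups=groups)


def compute_degrees(
    network: InteractionNetwork, cross_group_in_degrees: bool = True
) -> dict[str, int]:
    """Incident edge count per gene within the retained graph."""
    if cross_group_in_degrees:
        return {g: int(d) for g, d in network.graph.degree()}
    degrees = {g: 0 for g in network.graph.nodes}
    for u, v in network.graph.edges:
        if network.groups[u] == network.groups[v]:
            degrees[u] += 1
            degrees[v] += 1
    return degrees


def select_hubs(
    network: InteractionNetwork,
    n_shared: int = 20,
    n_each: int = 15,
    cross_group_in_degrees: bool = True,
) -> dict[str, HubSelection]:
    """Top-degree genes per group: ``n_shared`` for the shared group,
    ``n_each`` for each miRNA-exclusive group; ties broken by gene id."""
    degrees = compute_degrees(network, cross_group_in_degrees)
    selections = {}
    for group in GROUPS:
        members = network.group_members(group)
        limit = n_shared if group == GROUP_SHARED else n_each
        ordered = sorted(members, key=lambda g: (-degrees[g], g))
        hubs = ordered[:limit]
        if len(members) < limit:
            logger.info(
                "select_hubs: group %s has only %d genes (< %d requested)",
                group, len(members), limit,
            )
        selections[group] = HubSelection(
            group=group,
            hubs=hubs,
            degrees={g: degrees[g] for g in hubs},
            layout=circular_layout(hubs),
        )
    return selections


def circular_layout(hubs: Iterable[str]) -> dict[str, tuple[float, float]]:
    """Place hubs clockwise from angle 0 on the unit circle, evenly spaced."""
    hubs = list(hubs)
    n = len(hubs)
    layout = {}
    for i, gene in enumerate(hubs):
        theta = -2.0 * math.pi * i / n if n else 0.0
        layout[gene] = (math.cos(theta), math.sin(theta))
    return layout


def node_table(selections: Mapping[str, HubSelection]) -> pd.DataFrame:
    rows = []
    for group in GROUPS:
        sel = selections.get(group)
        if sel is None:
            continue
        for rank, gene in enumerate(sel.hubs, start=1):
            x, y = sel.layout[gene]
            rows.append((gene, group, sel.degrees[gene], rank, round(x, 6), round(y, 6)))
    return pd.DataFrame(rows, columns=["gene", "group", "degree", "rank", "x", "y"])


def within_group_edges(network: InteractionNetwork) -> pd.DataFrame:
    """Edge list for the layout export: between-group interactions hidden."""
    rows = [
        (min(u, v), max(u, v), d["confidence"])
        for u, v, d in network.graph.edges(data=True)
        if network.groups[u] == network.groups[v]
    ]
    return pd.DataFrame(sorted(rows), columns=["geneA", "geneB", "confidence"])


def write_network(
    selections: Mapping[str, HubSelection],
    network: InteractionNetwork,
    nodes_path: str | Path,
    edges_path: str | Path,
) -> None:
    node_table(selections).to_csv(nodes_path, sep="\t", index=False)
    within_group_edges(network).to_csv(edges_path, sep="\t", index=False)
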