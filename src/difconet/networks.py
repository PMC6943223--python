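"""Interaction networks over significant genes or pathways.

Given the list of significant entities (DEGs at gene level; enriched
pathways at pathway level, filtered at p <= 0.05) and a typed relation
table, builds the induced interaction network, annotates each node with its
regulation direction and degree, and ranks nodes by degree to nominate the
"core" entities that connect to many others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .relations import RelationTable, UNDIRECTED_TYPES

logger = logging.getLogger(__name__)


@dataclass
class InteractionNetwork:
    """Induced typed network; ``graph`` is a networkx MultiGraph.

    Node attributes: regulation (up/down), degree.  Edge attributes: type,
    directed, and for directed types the original source/target ids.
    """

    graph: nx.MultiGraph
    level: str = "gene"
    skipped_edges: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def isolated(self) -> list[str]:
        return sorted(n for n in self.graph if self.graph.degree(n) == 0)

    def node_table(self) -> pd.DataFrame:
        rows = [
            (n, self.graph.nodes[n].get("regulation", ""), self.graph.degree(n))
            for n in sorted(self.graph)
        ]
        return pd.DataFrame(rows, columns=["id", "regulation", "degree"])

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (d.get("source", u), d.get("target", v), d["type"])
            for u, v, d in self.graph.edges(data=True)
        ]
        rows.sort()
        return pd.DataFrame(rows, columns=["source", "target", "type"])


def build_network(significant: pd.DataFrame, relations: RelationTable,
                  p_threshold: float = 0.05, level: str = "gene") -> InteractionNetwork:
    """Induced subgraph of the relation table on the significant ids.

    ``significant`` needs columns ``id`` and ``regulation`` (up/down); an
    optional ``p_value`` column filters entries at ``p <= p_threshold``
    (pathway level).  Isolated retained nodes stay in the network.
    Self-loops are dropped; relations touching ids outside the namespace are
    skipped with a logged warning (annotation mismatch is expected).
    Undirected relation types deduplicate (u, v) with (v, u).
    """
    sig = significant.copy()
    if "p_value" in sig.columns:
        sig = sig[sig["p_value"] <= p_threshold]
    if sig["id"].duplicated().any():
        raise ValueError("duplicate ids in significant list")
    regulation = dict(zip(sig["id"], sig["regulation"]))

    g = nx.MultiGraph(level=level)
    for node in sorted(regulation):
        g.add_node(node, regulation=regulation[node])

    skipped: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()
    for row in relations.table.itertuples(index=False):
        u, v, etype = row.source, row.target, row.type
        if u == v:
            continue
        if u not in regulation or v not in regulation:
            skipped.append((u, v, etype))
            continue
        key = (u, v, etype) if etype not in UNDIRECTED_TYPES else (min(u, v), max(u, v), etype)
        if key in seen:
            continue
        seen.add(key)
        g.add_edge(u, v, type=etype, directed=bool(row.directed), source=u, target=v)
    if skipped:
        logger.warning("%d relation(s) skipped: endpoint not in the significant id list", len(skipped))

    for n in g:
        g.nodes[n]["degree"] = g.degree(n)
    return InteractionNetwork(graph=g, level=level, skipped_edges=skipped)


def rank_by_degree(net: InteractionNetwork) -> list[tuple[str, int]]:
    """Nodes ordered by descending degree, lexicographic id tie-break."""
    return sorted(
        ((n, net.graph.degree(n)) for n in net.graph),
        key=lambda item: (-item[1], item[0]),
    )


def write_network(net: InteractionNetwork, graphml_path: str | Path,
                  edges_path: str | Path, nodes_path: str | Path) -> None:
    nx.write_graphml(net.graph, str(graphml_path))
    net.edge_table().to_csv(edges_path, sep="\t", index=False)
    net.node_table().to_csv(nodes_path, sep="\t", index=False)
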