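"""Merge per-database SIFI networks into one Global Integrative Network.

Merging is pure set union on unified names: an edge is redundant exactly when
its (source, edge_type, target) triple already exists, in which case the
provenance tags union.  The operation is idempotent and independent of input
order.  A node reported with different kinds by different files is a hard
error — kinds are assigned at creation time, never inferred from names.

The non-human filter removes every edge incident to a non-human gene node and
the whole reaction (all edges of the intermediate) whenever an intermediate's
name embeds a non-human gene; orphaned nodes are dropped.  Humanness is
decided from organism annotation when the caller supplies it, else from
membership in the human gene table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from .diagnostics import Diagnostics
from .sifi_core import (
    COMPLEX,
    GENE,
    INTERMEDIATE,
    NodeAttr,
    SIFIEdge,
    intermediate_members,
)

logger = logging.getLogger(__name__)


@dataclass
class GINetwork:
    """Deduplicated directed network: edge triples with provenance + node attrs."""

    edges: dict[tuple[str, str, str], frozenset] = field(default_factory=dict)
    nodes: dict[str, NodeAttr] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_list(self) -> list[SIFIEdge]:
        return [
            SIFIEdge(*triple, self.edges[triple]) for triple in sorted(self.edges)
        ]

    def database_tags(self) -> set[str]:
        tags: set[str] = set()
        for provenance in self.edges.values():
            tags |= provenance
        return tags

    def kinds(self) -> dict[str, str]:
        return {node_id: attr.kind for node_id, attr in self.nodes.items()}

    def to_networkx(self):
        """Directed multigraph view (edge key = edge_type) for interop."""
        import networkx as nx

        graph = nx.MultiDiGraph()
        for node_id, attr in self.nodes.items():
            graph.add_node(node_id, kind=attr.kind, label=attr.label)
        for (source, edge_type, target), provenance in self.edges.items():
            graph.add_edge(
                source, target, key=edge_type,
                edge_type=edge_type, sources=sorted(provenance),
            )
        return graph


class NetworkComposition(NamedTuple):
    n_nodes: int
    n_edges: int
    n_genes: int
    n_chemicals: int
    n_complexes: int
    n_intermediates: int


def merge_sifi(
    inputs: Sequence[tuple[str, Sequence[SIFIEdge], Mapping[str, NodeAttr]]],
    diag: Diagnostics | None = None,
) -> GINetwork:
    """Union tagged SIFI networks into one GIN.

    Each input is (tag, edges, node_attrs).  An edge keeps its own provenance
    when it has any (re-merging merged networks), otherwise it is tagged with
    the input's tag.  Duplicate triples collapse with provenance union; node
    kind conflicts across files raise ValueError listing the offenders.
    """
    gin = GINetwork()
    kind_conflicts: dict[str, set[str]] = {}
    duplicates = 0
    for tag, edges, node_attrs in inputs:
        for edge in edges:
            provenance = edge.sources if edge.sources else frozenset({tag})
            triple = edge.triple()
            if triple in gin.edges:
                duplicates += 1
            gin.edges[triple] = gin.edges.get(triple, frozenset()) | provenance
        for node_id, attr in node_attrs.items():
            existing = gin.nodes.get(node_id)
            if existing is None:
                gin.nodes[node_id] = attr
            elif existing.kind != attr.kind:
                kind_conflicts.setdefault(node_id, set()).update(
                    {existing.kind, attr.kind}
                )
    if kind_conflicts:
        listing = "; ".join(
            f"{node}: {sorted(kinds)}" for node, kinds in sorted(kind_conflicts.items())
        )
        raise ValueError(f"node kind conflicts across inputs: {listing}")

    missing = _ensure_node_attrs(gin)
    if diag is not None:
        diag.count("merged_edges", gin.n_edges)
        diag.count("redundant_edges_collapsed", duplicates)
        if missing:
            diag.count("nodes_without_attrs_defaulted", missing)
    return gin


def _ensure_node_attrs(gin: GINetwork) -> int:
    """Guarantee every edge endpoint has a NodeAttr (defaulting conservatively)."""
    missing = 0
    for source, _, target in gin.edges:
        for node_id in (source, target):
            if node_id not in gin.nodes:
                missing += 1
                kind = INTERMEDIATE if ";" in node_id else GENE
                gin.nodes[node_id] = NodeAttr(node_id, kind, node_id)
    return missing


def filter_nonhuman(
    gin: GINetwork,
    human_gene_set: Iterable[str],
    known_nonhuman: Iterable[str] = (),
    diag: Diagnostics | None = None,
) -> GINetwork:
    """Remove edges involving non-human genes; drop orphaned nodes.

    A gene node is non-human when it is in ``known_nonhuman`` (organism
    annotation collected upstream) or absent from ``human_gene_set``.  Any
    edge incident to such a node goes, and so does every edge of an
    intermediate whose name embeds such a gene (the intermediate stands for
    a reaction the gene participates in).
    """
    human = set(human_gene_set)
    explicit = set(known_nonhuman)
    nonhuman_genes = {
        node_id
        for node_id, attr in gin.nodes.items()
        if attr.kind == GENE and (node_id in explicit or node_id not in human)
    }
    poisoned_intermediates = {
        node_id
        for node_id, attr in gin.nodes.items()
        if attr.kind == INTERMEDIATE
        and any(member in nonhuman_genes for member in intermediate_members(node_id))
    }
    banned = nonhuman_genes | poisoned_intermediates

    kept_edges = {
        triple: provenance
        for triple, provenance in gin.edges.items()
        if triple[0] not in banned and triple[2] not in banned
    }
    referenced = {node for source, _, target in kept_edges for node in (source, target)}
    kept_nodes = {
        node_id: attr for node_id, attr in gin.nodes.items() if node_id in referenced
    }
    removed_edges = gin.n_edges - len(kept_edges)
    if diag is not None:
        diag.count("nonhuman_gene_nodes", len(nonhuman_genes))
        diag.count("edges_removed_nonhuman", removed_edges)
        diag.count("nodes_removed_nonhuman", gin.n_nodes - len(kept_nodes))
    if removed_edges:
        logger.info(
            "non-human filter removed %d edges around %d genes",
            removed_edges, len(nonhuman_genes),
        )
    return GINetwork(edges=kept_edges, nodes=kept_nodes)


def count_composition(gin: GINetwork) -> NetworkComposition:
    """Node/edge counts by kind; kinds always sum to the node total."""
    per_kind = {GENE: 0, "chemical": 0, COMPLEX: 0, INTERMEDIATE: 0}
    for attr in gin.nodes.values():
        per_kind[attr.kind] += 1
    return NetworkComposition(
        n_nodes=gin.n_nodes,
        n_edges=gin.n_edges,
        n_genes=per_kind[GENE],
        n_chemicals=per_kind["chemical"],
        n_complexes=per_kind[COMPLEX],
        n_intermediates=per_kind[INTERMEDIATE],
    )
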