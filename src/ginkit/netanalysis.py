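"""Topology of the merged network: degrees, Leiden communities, subnetworks.

The GIN is a directed graph in which genes, chemicals and complexes connect
only through intermediate (reaction) nodes.  This module provides the
analyses run on the merged network: ranked degree tables, community
detection with the Leiden algorithm (python-igraph + leidenalg on the
directed graph, modularity objective by default), per-cluster node
composition and per-database edge contribution, and seed-based subnetwork
extraction with optional expansion to upstream regulators (the pattern used
to pull a metabolic pathway together with the kinases controlling its
enzymes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .merge import GINetwork
from .sifi_core import COMPLEX, CTRL, CTRL_NEG, CTRL_POS, GENE, INTERMEDIATE, PRO

logger = logging.getLogger(__name__)

CONTROL_EDGE_TYPES = (CTRL, CTRL_POS, CTRL_NEG)


@dataclass
class Partition:
    """Cluster assignment over all nodes; indices ranked by cluster size."""

    assignment: dict[str, int]
    quality: float = float("nan")

    def clusters(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, index in self.assignment.items():
            out.setdefault(index, set()).add(node)
        return out

    def sizes(self) -> list[int]:
        return [len(nodes) for _, nodes in sorted(self.clusters().items())]


def degree_table(gin: GINetwork, top_k: int) -> pd.DataFrame:
    """Top-k nodes by degree (in + out, each unique edge counted once).

    Ties break on node_id ascending.  Columns: node, label, kind, degree.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    degrees: dict[str, int] = {node: 0 for node in gin.nodes}
    for source, _, target in gin.edges:
        degrees[source] = degrees.get(source, 0) + 1
        degrees[target] = degrees.get(target, 0) + 1
    ranked = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    records = [
        {
            "node": node,
            "label": gin.nodes[node].label if node in gin.nodes else node,
            "kind": gin.nodes[node].kind if node in gin.nodes else "",
            "degree": degree,
        }
        for node, degree in ranked
    ]
    return pd.DataFrame(records)


def _to_igraph(gin: GINetwork):
    import igraph as ig

    nodes = sorted(gin.nodes)
    index = {node: i for i, node in enumerate(nodes)}
    pairs = sorted({(source, target) for source, _, target in gin.edges})
    graph = ig.Graph(
        n=len(nodes),
        edges=[(index[s], index[t]) for s, t in pairs],
        directed=True,
    )
    graph.vs["name"] = nodes
    return graph


def cluster_leiden(
    gin: GINetwork,
    resolution: float = 1.0,
    seed: int = 0,
    objective: str = "modularity",
) -> Partition:
    """Leiden community detection on the directed GIN.

    Parallel edge types between the same node pair are collapsed to one arc.
    ``objective`` is ``modularity`` (RB configuration null model, resolution
    parameter applies) or ``cpm``.  Deterministic given (graph, resolution,
    seed); cluster indices are relabelled by descending size (ties: smallest
    member node id).  Leiden guarantees connected communities, so nodes from
    different weakly connected components never share a cluster.
    """
    import leidenalg

    if gin.n_nodes == 0:
        return Partition(assignment={}, quality=0.0)
    graph = _to_igraph(gin)
    partition_type = {
        "modularity": leidenalg.RBConfigurationVertexPartition,
        "cpm": leidenalg.CPMVertexPartition,
    }[objective]
    raw = leidenalg.find_partition(
        graph, partition_type, resolution_parameter=resolution, seed=seed
    )
    membership = list(raw.membership)
    if objective == "modularity":
        # tiny components have fully degenerate (zero-gain) modularity ties
        # which Leiden resolves arbitrarily into singletons; collapse them
        # deterministically without ever decreasing the objective
        membership = _merge_zero_gain_clusters(graph, membership, resolution)
    members: dict[int, list[str]] = {}
    for vertex, cluster in zip(graph.vs["name"], membership):
        members.setdefault(cluster, []).append(vertex)
    ranked = sorted(members.values(), key=lambda nodes: (-len(nodes), min(nodes)))
    assignment = {
        node: rank for rank, nodes in enumerate(ranked) for node in nodes
    }
    return Partition(assignment=assignment, quality=raw.quality())


def _merge_zero_gain_clusters(graph, membership: list[int], resolution: float) -> list[int]:
    """Greedily merge edge-connected cluster pairs whose merge does not
    decrease directed modularity.

    Leiden is locally optimal, so only zero-gain merges ever fire; they
    occur when a component is too small for modularity to distinguish any
    split (every candidate partition scores 0).  Only pairs joined by at
    least one arc are considered, preserving component separation.  Ties
    break on the smallest cluster-index pair, so the result is
    deterministic.
    """
    m = graph.ecount()
    if m == 0:
        return membership
    membership = list(membership)
    arcs: dict[tuple[int, int], int] = {}
    k_out: dict[int, int] = {}
    k_in: dict[int, int] = {}
    for edge in graph.es:
        c_source = membership[edge.source]
        c_target = membership[edge.target]
        arcs[(c_source, c_target)] = arcs.get((c_source, c_target), 0) + 1
        k_out[c_source] = k_out.get(c_source, 0) + 1
        k_in[c_target] = k_in.get(c_target, 0) + 1

    def gain(c: int, d: int) -> float:
        cross = arcs.get((c, d), 0) + arcs.get((d, c), 0)
        null = (
            k_out.get(c, 0) * k_in.get(d, 0) + k_out.get(d, 0) * k_in.get(c, 0)
        ) / m
        return cross / m - resolution * null / m

    while True:
        candidates = sorted(
            {(min(c, d), max(c, d)) for (c, d) in arcs if c != d}
        )
        best = None
        for pair in candidates:
            delta = gain(*pair)
            if delta > -1e-12 and (best is None or delta > best[0] + 1e-12):
                best = (delta, pair)
        if best is None:
            return membership
        _, (keep, drop) = best
        membership = [keep if c == drop else c for c in membership]
        for (c, d), count in list(arcs.items()):
            if drop in (c, d):
                del arcs[(c, d)]
                nc = keep if c == drop else c
                nd = keep if d == drop else d
                arcs[(nc, nd)] = arcs.get((nc, nd), 0) + count
        k_out[keep] = k_out.get(keep, 0) + k_out.pop(drop, 0)
        k_in[keep] = k_in.get(keep, 0) + k_in.pop(drop, 0)


def cluster_composition(
    gin: GINetwork, partition: Partition, top_n: int = 20
) -> pd.DataFrame:
    """Node-kind composition of the top-n largest clusters.

    Columns: cluster, n_nodes, n_gene, n_chemical, n_complex, n_itmd; the
    kind columns sum to n_nodes row-wise.
    """
    records = []
    for cluster, nodes in sorted(partition.clusters().items()):
        counts = {GENE: 0, "chemical": 0, COMPLEX: 0, INTERMEDIATE: 0}
        for node in nodes:
            counts[gin.nodes[node].kind] += 1
        records.append(
            {
                "cluster": cluster,
                "n_nodes": len(nodes),
                "n_gene": counts[GENE],
                "n_chemical": counts["chemical"],
                "n_complex": counts[COMPLEX],
                "n_itmd": counts[INTERMEDIATE],
            }
        )
    frame = pd.DataFrame(records)
    if frame.empty:
        return pd.DataFrame(
            columns=["cluster", "n_nodes", "n_gene", "n_chemical", "n_complex", "n_itmd"]
        )
    return frame.sort_values(["n_nodes", "cluster"], ascending=[False, True]).head(
        top_n
    ).reset_index(drop=True)


def db_contribution(
    gin: GINetwork, partition: Partition
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster percentage (and log10 count) of edges from each database.

    An edge belongs to a cluster when both endpoints are inside it; boundary
    edges are excluded.  Because a shared edge counts once per contributing
    source, a cluster's percentages may sum above 100.  Clusters with zero
    internal edges get a zero row and a log message.
    """
    tags = sorted(gin.database_tags())
    clusters = sorted(partition.clusters())
    internal_counts = {cluster: 0 for cluster in clusters}
    per_db = {cluster: {tag: 0 for tag in tags} for cluster in clusters}
    for (source, _, target), provenance in gin.edges.items():
        c_source = partition.assignment.get(source)
        if c_source is None or c_source != partition.assignment.get(target):
            continue
        internal_counts[c_source] += 1
        for tag in provenance:
            per_db[c_source][tag] += 1

    pct_rows, log_rows = [], []
    for cluster in clusters:
        total = internal_counts[cluster]
        if total == 0:
            logger.info("cluster %d has no internal edges", cluster)
        pct_rows.append(
            {tag: 100.0 * per_db[cluster][tag] / total if total else 0.0 for tag in tags}
        )
        log_rows.append(
            {
                tag: math.log10(per_db[cluster][tag]) if per_db[cluster][tag] else float("-inf")
                for tag in tags
            }
        )
    index = pd.Index(clusters, name="cluster")
    return (
        pd.DataFrame(pct_rows, index=index),
        pd.DataFrame(log_rows, index=index),
    )


def _adjacency(gin: GINetwork):
    outgoing: dict[str, list[tuple[str, str, str]]] = {}
    incoming: dict[str, list[tuple[str, str, str]]] = {}
    for triple in gin.edges:
        outgoing.setdefault(triple[0], []).append(triple)
        incoming.setdefault(triple[2], []).append(triple)
    return outgoing, incoming


def subnetwork_enzymes(gin: GINetwork, nodes: Iterable[str]) -> set[str]:
    """Gene/complex nodes with a control edge into an intermediate of the set."""
    nodes = set(nodes)
    enzymes = set()
    for source, edge_type, target in gin.edges:
        if (
            edge_type in CONTROL_EDGE_TYPES
            and source in nodes
            and target in nodes
            and gin.nodes[source].kind in (GENE, COMPLEX)
        ):
            enzymes.add(source)
    return enzymes


def extract_subnetwork(
    gin: GINetwork,
    seed_nodes: Sequence[str],
    expand_regulators: bool = False,
) -> GINetwork:
    """Pull out the reactions around seed nodes, optionally with regulators.

    The core set is: the seeds, every intermediate adjacent to a seed, and
    all participants of those intermediates.  With ``expand_regulators``,
    for each enzyme in the core (gene/complex controlling a core
    intermediate) the intermediates producing it and those intermediates'
    controller nodes are added — i.e. the upstream reactions that modify the
    enzyme, typically PTMs by kinases.  The result is the induced edge set
    over the final node set, patched so no included intermediate is left
    without its substrate/controller side.
    """
    missing = sorted(set(seed_nodes) - set(gin.nodes))
    if missing:
        raise KeyError(f"unknown seed nodes: {', '.join(missing)}")
    outgoing, incoming = _adjacency(gin)

    def is_intermediate(node: str) -> bool:
        return gin.nodes[node].kind == INTERMEDIATE

    selected = set(seed_nodes)
    intermediates = set()
    for seed in seed_nodes:
        for _, _, target in outgoing.get(seed, []):
            if is_intermediate(target):
                intermediates.add(target)
        for source, _, _ in incoming.get(seed, []):
            if is_intermediate(source):
                intermediates.add(source)
    selected |= intermediates
    for intermediate in intermediates:
        for _, _, target in outgoing.get(intermediate, []):
            selected.add(target)
        for source, _, _ in incoming.get(intermediate, []):
            selected.add(source)

    if expand_regulators:
        enzymes = subnetwork_enzymes(gin, selected)
        for enzyme in enzymes:
            producers = {
                source
                for source, edge_type, _ in incoming.get(enzyme, [])
                if edge_type == PRO and is_intermediate(source)
            }
            selected |= producers
            for producer in producers:
                for source, edge_type, _ in incoming.get(producer, []):
                    if edge_type in CONTROL_EDGE_TYPES:
                        selected.add(source)

    kept = {
        triple: provenance
        for triple, provenance in gin.edges.items()
        if triple[0] in selected and triple[2] in selected
    }
    # an intermediate must keep at least one incoming member edge
    for node in [n for n in selected if is_intermediate(n)]:
        has_incoming = any(triple in kept for triple in incoming.get(node, []))
        if not has_incoming:
            for triple in incoming.get(node, []):
                selected.add(triple[0])
                kept[triple] = gin.edges[triple]
    nodes = {
        node: gin.nodes[node]
        for node in selected
        if node in gin.nodes
    }
    return GINetwork(edges=kept, nodes=nodes)
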