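"""Degrees, Leiden clustering, composition/contribution, extraction."""

from __future__ import annotations

import math

import networkx as nx
import pytest

from ginkit.merge import merge_sifi
from ginkit.netanalysis import (
    cluster_composition,
    cluster_leiden,
    db_contribution,
    degree_table,
    extract_subnetwork,
)
from ginkit.reaction_extract import ACTIVATION, Reaction
from ginkit.sifi_core import NodeAttr, SIFIEdge, reactions_to_sifi
from ginkit.synthetic import glycolysis_like_chain, planted_communities


def _gin_from_reactions(reactions, kinds, tag="db"):
    edges, nodes, _ = reactions_to_sifi(reactions, kinds, tag)
    return merge_sifi([(tag, edges, nodes)])


def _star_gin():
    # hub chemical feeding six reactions
    kinds = {"HUB": "chemical"}
    reactions = []
    for i in range(6):
        kinds[f"P{i}"] = "chemical"
        kinds[f"E{i}"] = "gene"
        reactions.append(
            Reaction(f"r{i}", "BiochemicalReaction", ("HUB",), (f"P{i}",), ((f"E{i}", ACTIVATION),))
        )
    return _gin_from_reactions(reactions, kinds)


def test_degree_counts_unique_edges():
    gin = _star_gin()
    table = degree_table(gin, top_k=1)
    assert table.iloc[0]["node"] == "HUB"
    assert table.iloc[0]["degree"] == 6  # one sub edge per reaction


def test_degree_tie_break_and_errors():
    gin = _star_gin()
    table = degree_table(gin, top_k=50)
    degrees = list(table["degree"])
    assert degrees == sorted(degrees, reverse=True)
    threes = [r["node"] for _, r in table.iterrows() if r["degree"] == 3]
    assert threes == sorted(threes)  # ties broken by node id
    with pytest.raises(ValueError):
        degree_table(gin, top_k=0)


def test_empty_network_degree_table():
    assert degree_table(merge_sifi([]), top_k=5).empty


def test_disjoint_components_never_share_cluster():
    """Two disjoint reaction stars: clusters match the weakly connected
    components (oracle: networkx components on the exported graph)."""
    kinds = {}
    reactions = []
    for block in ("A", "B"):
        kinds[f"{block}HUB"] = "chemical"
        for i in range(5):
            kinds[f"{block}P{i}"] = "chemical"
            kinds[f"{block}E{i}"] = "gene"
            reactions.append(
                Reaction(
                    f"{block}r{i}", "BiochemicalReaction",
                    (f"{block}HUB",), (f"{block}P{i}",), ((f"{block}E{i}", ACTIVATION),),
                )
            )
    gin = _gin_from_reactions(reactions, kinds)
    partition = cluster_leiden(gin, seed=1)
    components = list(nx.weakly_connected_components(gin.to_networkx()))
    assert len(components) == 2
    for component in components:
        clusters_of_other = {
            partition.assignment[n] for n in gin.nodes if n not in component
        }
        clusters_here = {partition.assignment[n] for n in component}
        assert clusters_here.isdisjoint(clusters_of_other)


def test_single_reaction_single_cluster():
    kinds = {"a": "chemical", "b": "chemical", "e": "gene"}
    gin = _gin_from_reactions(
        [Reaction("r", "BiochemicalReaction", ("a",), ("b",), (("e", ACTIVATION),))], kinds
    )
    partition = cluster_leiden(gin, seed=0)
    assert len(set(partition.assignment.values())) == 1


def test_clustering_deterministic_given_seed():
    gin, _ = planted_communities(seed=2)
    p1 = cluster_leiden(gin, seed=5)
    p2 = cluster_leiden(gin, seed=5)
    assert p1.assignment == p2.assignment


def test_planted_communities_recovered():
    from sklearn.metrics import adjusted_rand_score

    gin, labels = planted_communities(seed=3)
    nodes = sorted(labels)
    scores = []
    for seed in range(10):
        partition = cluster_leiden(gin, resolution=1.0, seed=seed)
        scores.append(
            adjusted_rand_score(
                [labels[n] for n in nodes], [partition.assignment[n] for n in nodes]
            )
        )
    assert min(scores) >= 0.9


def test_cluster_composition_conserves_sizes():
    gin, _ = planted_communities(seed=4)
    partition = cluster_leiden(gin, seed=0)
    frame = cluster_composition(gin, partition, top_n=50)
    kind_sum = frame[["n_gene", "n_chemical", "n_complex", "n_itmd"]].sum(axis=1)
    assert (kind_sum == frame["n_nodes"]).all()
    assert frame["n_nodes"].sum() == gin.n_nodes  # all clusters fit in top_n here
    assert frame.loc[0, "n_complex"] == 0


def test_db_contribution_single_source_cluster():
    kinds = {"a": "chemical", "b": "chemical", "e": "gene"}
    gin = _gin_from_reactions(
        [Reaction("r", "BiochemicalReaction", ("a",), ("b",), (("e", ACTIVATION),))],
        kinds, tag="db1",
    )
    partition = cluster_leiden(gin, seed=0)
    pct, log10 = db_contribution(gin, partition)
    assert (pct["db1"] == 100.0).all()
    assert (log10["db1"] == math.log10(3)).all()


def test_db_contribution_shared_edge_exceeds_100_percent():
    edges = [SIFIEdge("a", "sub", "i", frozenset({"db1", "db2"}))]
    nodes = {
        "a": NodeAttr("a", "chemical", "a"),
        "i": NodeAttr("i", "intermediate", "i"),
    }
    gin = merge_sifi([("x", edges, nodes)])
    from ginkit.netanalysis import Partition

    partition = Partition(assignment={"a": 0, "i": 0})
    pct, _ = db_contribution(gin, partition)
    assert pct.loc[0, "db1"] == 100.0 and pct.loc[0, "db2"] == 100.0


def test_db_contribution_matches_recount_on_two_db_network():
    """Brute-force recount of internal edges per (cluster, database)."""
    gin, _ = planted_communities(seed=6)
    # fake a second source on half the edges
    edges = gin.edge_list()
    retagged = []
    for i, edge in enumerate(edges):
        tags = frozenset({"dbA", "dbB"}) if i % 2 else frozenset({"dbA"})
        retagged.append(SIFIEdge(*edge.triple(), tags))
    gin2 = merge_sifi([("x", retagged, gin.nodes)])
    partition = cluster_leiden(gin2, seed=0)
    pct, _ = db_contribution(gin2, partition)
    for cluster in pct.index:
        internal = [
            (t, prov) for t, prov in gin2.edges.items()
            if partition.assignment[t[0]] == cluster
            and partition.assignment[t[2]] == cluster
        ]
        for tag in ("dbA", "dbB"):
            expected = sum(1 for _, prov in internal if tag in prov)
            got = pct.loc[cluster, tag] * len(internal) / 100.0 if internal else 0.0
            assert round(got) == expected


class TestExtraction:
    def test_single_reaction_from_one_substrate(self):
        kinds = {"a": "chemical", "b": "chemical", "e": "gene"}
        gin = _gin_from_reactions(
            [Reaction("r", "BiochemicalReaction", ("a",), ("b",), (("e", ACTIVATION),))], kinds
        )
        sub = extract_subnetwork(gin, ["a"])
        assert set(sub.edges) == set(gin.edges)
        assert set(sub.nodes) == set(gin.nodes)

    def test_isolated_seed_yields_single_node(self):
        kinds = {"a": "chemical", "b": "chemical", "e": "gene", "lone": "chemical"}
        edges, nodes, _ = reactions_to_sifi(
            [Reaction("r", "BiochemicalReaction", ("a",), ("b",), (("e", ACTIVATION),))],
            kinds, "db",
        )
        nodes["lone"] = NodeAttr("lone", "chemical", "lone")
        gin = merge_sifi([("db", edges, nodes)])
        sub = extract_subnetwork(gin, ["lone"])
        assert set(sub.nodes) == set() or set(sub.nodes) == {"lone"}
        assert sub.n_edges == 0

    def test_unknown_seed_is_error(self):
        gin = _star_gin()
        with pytest.raises(KeyError, match="GHOST"):
            extract_subnetwork(gin, ["GHOST"])

    def test_planted_regulators_recovered_exactly(self):
        gin, info = glycolysis_like_chain(seed=5)
        sub = extract_subnetwork(gin, info["seeds"], expand_regulators=True)
        genes = {n for n, a in sub.nodes.items() if a.kind == "gene"}
        assert genes == set(info["enzymes"]) | set(info["regulators"])
        # without expansion: enzymes only, no kinases
        core = extract_subnetwork(gin, info["seeds"], expand_regulators=False)
        core_genes = {n for n, a in core.nodes.items() if a.kind == "gene"}
        assert core_genes == set(info["enzymes"])

    def test_output_is_valid_network(self):
        gin, info = glycolysis_like_chain(seed=8)
        sub = extract_subnetwork(gin, info["seeds"], expand_regulators=True)
        for source, _, target in sub.edges:
            assert source in sub.nodes and target in sub.nodes
        for node, attr in sub.nodes.items():
            if attr.kind == "intermediate":
                assert any(t[2] == node for t in sub.edges)  # never dangling
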