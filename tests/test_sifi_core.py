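"""Meta-pathway conversion laws and SIFI file round-trips."""

from __future__ import annotations

import random

import pytest

from ginkit.diagnostics import Diagnostics
from ginkit.reaction_extract import ACTIVATION, INHIBITION, UNKNOWN, Reaction
from ginkit.sifi_core import (
    NodeAttr,
    SIFIEdge,
    export_sif,
    intermediate_base_name,
    reaction_to_sifi,
    reactions_to_sifi,
    read_sifi,
    write_sifi,
)

KINDS = {
    "CIDa": "chemical", "CIDb": "chemical", "CIDc": "chemical", "CIDd": "chemical",
    "GENE1": "gene", "PROT1": "gene", "KIN1": "gene", "X": "chemical",
}


def test_metabolic_reaction_shape():
    reaction = Reaction(
        "r", "BiochemicalReaction",
        substrates=("CIDa", "CIDb"), products=("CIDc", "CIDd"),
        controllers=(("GENE1", ACTIVATION),),
    )
    node, edges = reaction_to_sifi(reaction, "db")
    assert node.name == "CIDa;CIDb;GENE1"
    assert len(edges) == 5
    triples = {e.triple() for e in edges}
    assert ("CIDa", "sub", node.name) in triples
    assert ("GENE1", "ctrl+", node.name) in triples
    assert (node.name, "pro", "CIDc") in triples and (node.name, "pro", "CIDd") in triples


def test_ptm_reaction_keeps_substrate_name_for_product():
    """A signaling (PTM) reaction: substrate and product are the same
    protein; the kinase enters via a control edge."""
    reaction = Reaction(
        "r", "BiochemicalReaction",
        substrates=("PROT1",), products=("PROT1",),
        controllers=(("KIN1", ACTIVATION),),
    )
    node, edges = reaction_to_sifi(reaction, "db")
    assert node.name == "PROT1;KIN1"
    assert {e.triple() for e in edges} == {
        ("PROT1", "sub", "PROT1;KIN1"),
        ("KIN1", "ctrl+", "PROT1;KIN1"),
        ("PROT1;KIN1", "pro", "PROT1"),
    }


def test_degenerate_degradation_flagged():
    reaction = Reaction("r", "Degradation", substrates=("X",), products=())
    diag = Diagnostics()
    edges, nodes, intermediates = reactions_to_sifi([reaction], KINDS, "db", diag)
    assert [e.triple() for e in edges] == [("X", "sub", "X")]
    assert diag["degenerate_self_named_intermediates"] == 1
    assert nodes["X"].kind == "chemical"  # member kind wins


def test_unconvertible_reaction_dropped_counted():
    reaction = Reaction("r", "Conversion", substrates=(), products=("CIDa",))
    diag = Diagnostics()
    edges, _, intermediates = reactions_to_sifi([reaction], KINDS, "db", diag)
    assert edges == [] and intermediates == []
    assert diag["reactions_unconvertible"] == 1


def _random_reaction(rng: random.Random, index: int) -> Reaction:
    substrates = tuple(f"S{index}_{i}" for i in range(rng.randint(0, 3)))
    controllers = tuple(
        (f"E{index}_{i}", rng.choice((ACTIVATION, INHIBITION, UNKNOWN)))
        for i in range(rng.randint(0, 2))
    )
    if not substrates and not controllers:
        substrates = (f"S{index}_0",)
    cofactors = tuple(f"C{index}_{i}" for i in range(rng.randint(0, 1)))
    products = tuple(f"P{index}_{i}" for i in range(rng.randint(0, 2)))
    return Reaction(
        f"r{index}", "BiochemicalReaction", substrates, products, controllers, cofactors
    )


def test_conversion_law_on_random_reactions():
    """For 1000 random reactions: exactly one intermediate each, and edge
    count = |substrates| + |controllers| + |cofactors| + |products|."""
    rng = random.Random(42)
    for index in range(1000):
        reaction = _random_reaction(rng, index)
        node, edges = reaction_to_sifi(reaction, "db")
        expected = (
            len(set(reaction.substrates))
            + len(reaction.controllers)
            + len(set(reaction.cofactors))
            + len(set(reaction.products))
        )
        assert len(edges) == expected
        intermediates = {e.target for e in edges if e.edge_type != "pro"} | {
            e.source for e in edges if e.edge_type == "pro"
        }
        assert intermediates == {node.name}


def test_regrouping_edges_reconstructs_reaction():
    """Inverse mapping: grouping a reaction's edges by intermediate recovers
    (substrates, controllers∪cofactors, products) exactly."""
    rng = random.Random(43)
    for index in range(300):
        reaction = _random_reaction(rng, index)
        node, edges = reaction_to_sifi(reaction, "db")
        subs = {e.source for e in edges if e.edge_type == "sub"}
        ctrl = {e.source for e in edges if e.edge_type.startswith("ctrl")}
        prods = {e.target for e in edges if e.edge_type == "pro"}
        assert subs == set(reaction.substrates)
        assert ctrl == {c for c, _ in reaction.controllers} | set(reaction.cofactors)
        assert prods == set(reaction.products)


def test_intermediate_name_invariant_under_participant_permutation():
    members_a = intermediate_base_name(["B", "A", "C"], ["Z", "E"])
    members_b = intermediate_base_name(["C", "A", "B"], ["E", "Z"])
    assert members_a == members_b == "A;B;C;E;Z"


def test_identical_reactions_from_two_databases_share_intermediate():
    reaction = Reaction(
        "r", "BiochemicalReaction", ("CIDa",), ("CIDb",), (("GENE1", ACTIVATION),)
    )
    node1, _ = reaction_to_sifi(reaction, "db1")
    node2, _ = reaction_to_sifi(reaction, "db2")
    assert node1.name == node2.name


def test_product_collision_disambiguated_with_suffix():
    """Same substrates+enzyme, different products: every colliding reaction
    gets its own ';#k' intermediate."""
    r1 = Reaction("r1", "BiochemicalReaction", ("CIDa",), ("CIDb",), (("GENE1", ACTIVATION),))
    r2 = Reaction("r2", "BiochemicalReaction", ("CIDa",), ("CIDc",), (("GENE1", ACTIVATION),))
    diag = Diagnostics()
    edges, nodes, intermediates = reactions_to_sifi(
        [r1, r2], KINDS | {"CIDe": "chemical"}, "db", diag
    )
    names = sorted(i.name for i in intermediates)
    assert names == ["CIDa;GENE1;#1", "CIDa;GENE1;#2"]
    assert diag["intermediate_name_collisions"] > 0
    # no collision → no suffix
    _, _, only = reactions_to_sifi([r1], KINDS, "db")
    assert only[0].name == "CIDa;GENE1"


def test_round_trip_and_determinism(tmp_path):
    rng = random.Random(44)
    reactions = [_random_reaction(rng, i) for i in range(60)]
    kinds = {}
    edges, nodes, _ = reactions_to_sifi(reactions, kinds, "dbX")
    path = tmp_path / "net.sifi"
    write_sifi(edges, nodes, path)
    back_edges, back_nodes = read_sifi(path)
    # set-equality including provenance
    def normalise(edge_list):
        grouped: dict[tuple, set] = {}
        for e in edge_list:
            grouped.setdefault(e.triple(), set()).update(e.sources)
        return {k: frozenset(v) for k, v in grouped.items()}
    assert normalise(back_edges) == normalise(edges)
    assert back_nodes == nodes
    # byte-identical on rewrite (canonical sort order)
    first = path.read_bytes()
    write_sifi(back_edges, back_nodes, path)
    assert path.read_bytes() == first


def test_empty_network_round_trip(tmp_path):
    path = tmp_path / "empty.sifi"
    write_sifi([], {}, path)
    edges, nodes = read_sifi(path)
    assert edges == [] and nodes == {}


def test_malformed_line_error_names_line(tmp_path):
    path = tmp_path / "bad.sifi"
    path.write_text("source\tedge_type\ttarget\tsources\na\tb\n")
    with pytest.raises(ValueError, match=r"bad\.sifi:2"):
        read_sifi(path)


def test_sif_export_drops_provenance(tmp_path):
    edges = [SIFIEdge("a", "sub", "a;e", frozenset({"db1", "db2"}))]
    path = tmp_path / "net.sif"
    export_sif(edges, path)
    assert path.read_text() == "a\tsub\ta;e\n"
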