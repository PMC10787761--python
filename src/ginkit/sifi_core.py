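"""SIFI: the Simple Interaction Format with Intermediates.

Signaling and metabolic networks draw incompatible edges — "kinase activates
protein" versus "substrate becomes product".  The meta-pathway construction
reconciles them by giving every biochemical reaction one *intermediate node*
standing for the transient substrate–enzyme encounter: substrates and
controllers point into the intermediate, the intermediate points to products.
A phosphorylation and a metabolic conversion then have the same topological
shape, and a whole pathway collection becomes one directed graph.

Edge vocabulary (column 2 of a SIFI file):

======  =============================================
sub     substrate → intermediate
ctrl    controller of unknown sign, or cofactor → intermediate
ctrl+   activating controller → intermediate
ctrl-   inhibiting controller → intermediate
pro     intermediate → product
======  =============================================

The intermediate is named by its members — sorted substrates, then sorted
controllers, joined by ``;`` — and names are built *after* identifier
unification, so the same reaction recorded by two databases yields the same
intermediate and its edges coincide when merged.  Distinct reactions sharing
substrates+controllers but differing in products are disambiguated with a
``;#k`` suffix (k indexed over the sorted distinct product sets) so each
intermediate still denotes exactly one reaction.

File dialect: UTF-8, tab-separated, one header line, columns
``source  edge_type  target  sources`` (provenance comma-joined); a companion
``<stem>.nodes.tsv`` carries ``node  kind  label``.  The first three columns
are plain SIF and load directly in Cytoscape; :func:`export_sif` writes that
reduced form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from .diagnostics import Diagnostics
from .reaction_extract import ACTIVATION, INHIBITION, Reaction

logger = logging.getLogger(__name__)

SUB = "sub"
CTRL = "ctrl"
CTRL_POS = "ctrl+"
CTRL_NEG = "ctrl-"
PRO = "pro"
EDGE_TYPES = frozenset({SUB, CTRL, CTRL_POS, CTRL_NEG, PRO})

_SIGN_TO_EDGE = {ACTIVATION: CTRL_POS, INHIBITION: CTRL_NEG}

GENE = "gene"
CHEMICAL = "chemical"
COMPLEX = "complex"
INTERMEDIATE = "intermediate"
NODE_KINDS = (GENE, CHEMICAL, COMPLEX, INTERMEDIATE)


class SIFIEdge(NamedTuple):
    source: str
    edge_type: str
    target: str
    sources: frozenset = frozenset()

    def triple(self) -> tuple[str, str, str]:
        return (self.source, self.edge_type, self.target)


class NodeAttr(NamedTuple):
    node_id: str
    kind: str
    label: str


@dataclass
class IntermediateNode:
    name: str
    member_substrates: tuple[str, ...]
    member_controllers: tuple[str, ...]


def intermediate_base_name(substrates: Iterable[str], controllers: Iterable[str]) -> str:
    """Sorted substrates, then sorted controllers, joined by ';'."""
    members = sorted(set(substrates)) + sorted(set(controllers))
    return ";".join(members)


def intermediate_members(name: str) -> list[str]:
    """Member tokens of an intermediate name (the ';#k' suffix is not one)."""
    return [token for token in name.split(";") if not token.startswith("#")]


def reaction_to_sifi(
    reaction: Reaction,
    source_db: str | None = None,
    name_suffix: str = "",
) -> tuple[IntermediateNode, list[SIFIEdge]]:
    """Convert one unified reaction to its intermediate node and edges.

    Edge count is |substrates| + |controllers| + |cofactors| + |products|
    (participants as sets).  A reaction with neither substrates nor
    controllers cannot name an intermediate and raises ValueError; callers
    batching reactions drop and count those.
    """
    substrates = tuple(sorted(set(reaction.substrates)))
    controller_names = tuple(sorted({name for name, _ in reaction.controllers}))
    if not substrates and not controller_names:
        raise ValueError(
            f"reaction {reaction.reaction_id}: no substrates and no controllers, "
            "cannot name an intermediate"
        )
    name = intermediate_base_name(substrates, controller_names) + name_suffix
    provenance = frozenset({source_db or reaction.source_db} - {""})

    edges = [SIFIEdge(s, SUB, name, provenance) for s in substrates]
    sign_by_controller: dict[str, set[str]] = {}
    for controller, sign in reaction.controllers:
        sign_by_controller.setdefault(controller, set()).add(sign)
    for controller in controller_names:
        signs = sign_by_controller[controller]
        # a controller reported with several signs contributes one edge per sign
        for sign in sorted(signs):
            edges.append(SIFIEdge(controller, _SIGN_TO_EDGE.get(sign, CTRL), name, provenance))
    for cofactor in sorted(set(reaction.cofactors)):
        edges.append(SIFIEdge(cofactor, CTRL, name, provenance))
    for product in sorted(set(reaction.products)):
        edges.append(SIFIEdge(name, PRO, product, provenance))

    node = IntermediateNode(
        name=name,
        member_substrates=substrates,
        member_controllers=controller_names,
    )
    return node, edges


def reactions_to_sifi(
    reactions: Sequence[Reaction],
    node_kinds: Mapping[str, str],
    source_db: str | None = None,
    diag: Diagnostics | None = None,
) -> tuple[list[SIFIEdge], dict[str, NodeAttr], list[IntermediateNode]]:
    """Convert a batch of unified reactions, handling name collisions.

    When several distinct reactions share substrates+controllers but differ
    in products, every colliding intermediate gets a ``;#k`` suffix with k
    the 1-based rank of the reaction's sorted product set among the distinct
    product sets.  Reactions that cannot name an intermediate, and the
    degenerate single-member case where the intermediate name equals an
    existing participant name, are counted in diagnostics.
    """
    groups: dict[str, dict[tuple[str, ...], list[Reaction]]] = {}
    unconvertible = 0
    for reaction in reactions:
        substrates = set(reaction.substrates)
        controllers = {name for name, _ in reaction.controllers}
        if not substrates and not controllers:
            unconvertible += 1
            logger.info(
                "dropping reaction %s: cannot name an intermediate", reaction.reaction_id
            )
            continue
        base = intermediate_base_name(substrates, controllers)
        products = tuple(sorted(set(reaction.products)))
        groups.setdefault(base, {}).setdefault(products, []).append(reaction)

    edges: list[SIFIEdge] = []
    nodes: dict[str, NodeAttr] = {}
    intermediates: list[IntermediateNode] = []

    def note_node(name: str, kind: str) -> None:
        if name not in nodes:
            nodes[name] = NodeAttr(name, kind, name)

    for base in sorted(groups):
        by_products = groups[base]
        collided = len(by_products) > 1
        for k, products in enumerate(sorted(by_products), start=1):
            suffix = f";#{k}" if collided else ""
            if collided and diag is not None:
                diag.count("intermediate_name_collisions")
            for reaction in by_products[products]:
                node, reaction_edges = reaction_to_sifi(reaction, source_db, suffix)
                members = set(node.member_substrates) | set(node.member_controllers)
                if len(members) == 1 and not suffix:
                    # degenerate: the intermediate name IS its sole member
                    # (e.g. uncontrolled single-substrate degradation); the
                    # node keeps the member's kind so the same molecule seen
                    # elsewhere does not change kind
                    if diag is not None:
                        diag.count("degenerate_self_named_intermediates")
                    member = next(iter(members))
                    logger.warning(
                        "degenerate intermediate %r equals its member node", node.name
                    )
                    note_node(node.name, node_kinds.get(member, GENE))
                else:
                    note_node(node.name, INTERMEDIATE)
                intermediates.append(node)
                edges.extend(reaction_edges)
                for participant in reaction.participants():
                    note_node(participant, node_kinds.get(participant, GENE))

    if diag is not None:
        diag.count("reactions_converted", len(intermediates))
        if unconvertible:
            diag.count("reactions_unconvertible", unconvertible)
    return edges, nodes, intermediates


# ---------------------------------------------------------------------------
# file I/O

_HEADER = ["source", "edge_type", "target", "sources"]


def _nodes_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".nodes.tsv")


def write_sifi(
    edges: Iterable[SIFIEdge],
    node_attrs: Mapping[str, NodeAttr],
    path: str | Path,
) -> None:
    """Write a SIFI file and its companion node table.

    Canonical order — edges by (source, edge_type, target), nodes by id —
    so rewriting the same network is byte-identical.
    """
    path = Path(path)
    unique: dict[tuple[str, str, str], set[str]] = {}
    for edge in edges:
        unique.setdefault(edge.triple(), set()).update(edge.sources)
    with path.open("w", encoding="utf-8", newline="\n") as handle:
        handle.write("\t".join(_HEADER) + "\n")
        for triple in sorted(unique):
            provenance = ",".join(sorted(unique[triple]))
            handle.write("\t".join((*triple, provenance)) + "\n")
    with _nodes_path(path).open("w", encoding="utf-8", newline="\n") as handle:
        handle.write("node\tkind\tlabel\n")
        for node_id in sorted(node_attrs):
            attr = node_attrs[node_id]
            handle.write(f"{attr.node_id}\t{attr.kind}\t{attr.label}\n")


def read_sifi(path: str | Path) -> tuple[list[SIFIEdge], dict[str, NodeAttr]]:
    """Read a SIFI file (and its node table when present); lossless inverse
    of :func:`write_sifi`.  A line with fewer than 3 or more than 4 fields is
    an error naming the line number."""
    path = Path(path)
    edges: list[SIFIEdge] = []
    with path.open("r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if lineno == 1 or not line:
                continue
            fields = line.split("\t")
            if len(fields) == 3:
                source, edge_type, target = fields
                provenance: frozenset = frozenset()
            elif len(fields) == 4:
                source, edge_type, target, tags = fields
                provenance = frozenset(t for t in tags.split(",") if t)
            else:
                raise ValueError(
                    f"{path}:{lineno}: expected 3-4 tab-separated fields, got {len(fields)}"
                )
            edges.append(SIFIEdge(source, edge_type, target, provenance))

    nodes: dict[str, NodeAttr] = {}
    nodes_file = _nodes_path(path)
    if nodes_file.exists():
        with nodes_file.open("r", encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if lineno == 1 or not line:
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise ValueError(
                        f"{nodes_file}:{lineno}: expected 3 fields, got {len(fields)}"
                    )
                nodes[fields[0]] = NodeAttr(*fields)
    return edges, nodes


def export_sif(edges: Iterable[SIFIEdge], path: str | Path) -> None:
    """Plain 3-column SIF (no header, provenance dropped) for Cytoscape."""
    triples = sorted({edge.triple() for edge in edges})
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        for triple in triples:
            handle.write("\t".join(triple) + "\n")
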