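"""Synthetic BioPAX level-3 documents with known ground truth.

Every stage of the conversion pipeline is tested against data generated
here: small OWL documents containing metabolic conversions, transports,
degradations, complex assemblies and PTM (signaling) reactions, with
Catalysis/Control/Modulation controllers, nested complexes, multi-source
chemical xrefs drawn from a planted synonym table, a planted fraction of
reactions shared between databases, and a planted share of reactions
involving non-human genes.  The generator keeps its own bookkeeping — the
unified names, edges, node kinds and overlaps the pipeline *should*
produce — computed with plain set logic independent of the conversion code,
and that bookkeeping is the oracle for the end-to-end tests.

Identifiers live in a reserved namespace (``GENE###``, ``XGENE###``,
``CID9####9`` ...) so no accidental dependence on real mapping tables can
creep in.  Generation is fully deterministic given the spec's seed.

What the generator does *not* emulate: the heavy-tailed degree distributions
of real knowledge bases, database-specific naming quirks and special
characters, compartments, stoichiometry, and literature-sized documents.

Two further fixtures for the network-analysis layer are built directly as
merged networks: a planted-community graph (dense reaction blocks, sparse
cross wiring) for clustering recovery, and a glycolysis-like reaction chain
with planted kinase regulators for subnetwork extraction.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from lxml import etree

from .merge import GINetwork, merge_sifi
from .reaction_extract import ACTIVATION, INHIBITION, UNKNOWN, Reaction
from .sifi_core import NodeAttr, reactions_to_sifi

_BP = "http://www.biopax.org/release/biopax-level3.owl#"
_RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
_OWL = "http://www.w3.org/2002/07/owl#"
_XSD = "http://www.w3.org/2001/XMLSchema#"

_SIGN_TO_EDGE = {ACTIVATION: "ctrl+", INHIBITION: "ctrl-", UNKNOWN: "ctrl"}

#: UC_ID source types in precedence order, with the planted external-id
#: pattern and the unified string it must map to.  Kept local on purpose:
#: the bookkeeping here is the oracle for the unification code.
_CHEM_SOURCES = ("CID", "SID", "CAS", "KEGG", "HMDB", "ChEBI")
_DB_SPELLINGS = {
    "CID": ("PubChem-compound", "pubchem compound"),
    "SID": ("PubChem-substance", "pubchem-substance"),
    "CAS": ("CAS", "cas"),
    "KEGG": ("KEGG Compound", "kegg"),
    "HMDB": ("HMDB", "hmdb"),
    "ChEBI": ("ChEBI", "chebi"),
}
_UNIPROT_SPELLINGS = ("UniProt", "uniprot knowledgebase", "UniProt")

HUMAN = "Homo sapiens"
NONHUMAN = "Mus musculus"


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic multi-database corpus."""

    n_databases: int = 3
    n_genes: int = 30
    n_chemicals: int = 40
    reactions_per_db: int = 50
    fraction_signaling: float = 0.4
    overlap_fraction: float = 0.2
    complex_rate: float = 0.15
    nonhuman_rate: float = 0.08
    xref_multiplicity: tuple[int, int] = (1, 3)
    seed: int = 0

    def validate(self) -> None:
        for name in ("fraction_signaling", "overlap_fraction", "complex_rate", "nonhuman_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in ("n_databases", "n_genes", "n_chemicals", "reactions_per_db"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.overlap_fraction > 0 and self.n_databases < 2:
            raise ValueError("overlap_fraction > 0 requires at least 2 databases")
        lo, hi = self.xref_multiplicity
        if not 1 <= lo <= hi:
            raise ValueError("xref_multiplicity must be a range with 1 <= lo <= hi")


@dataclass
class PlantedReaction:
    """One reaction of the universe, in unified (post-mapping) names."""

    rid: str
    rclass: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    controllers: tuple[tuple[str, str], ...]  # (unified name, sign)
    cofactors: tuple[str, ...]
    control_class: str | None  # Catalysis / Control / Modulation / None
    complexes: dict[str, tuple] = field(default_factory=dict)  # name -> structure
    nonhuman: bool = False

    def intermediate(self) -> str:
        members = sorted(set(self.substrates)) + sorted(
            {name for name, _ in self.controllers}
        )
        return ";".join(members)

    def edges(self) -> set[tuple[str, str, str]]:
        node = self.intermediate()
        triples = {(s, "sub", node) for s in self.substrates}
        triples |= {
            (name, _SIGN_TO_EDGE[sign], node) for name, sign in self.controllers
        }
        triples |= {(c, "ctrl", node) for c in self.cofactors}
        triples |= {(node, "pro", p) for p in self.products}
        return triples


@dataclass
class DbTruth:
    reactions: list[PlantedReaction] = field(default_factory=list)
    edges: set = field(default_factory=set)
    genes: set = field(default_factory=set)
    chemicals: set = field(default_factory=set)
    complexes: set = field(default_factory=set)
    intermediates: set = field(default_factory=set)


@dataclass
class GroundTruth:
    """What the pipeline should reconstruct, by the generator's own count."""

    tags: tuple[str, ...]
    per_db: dict[str, DbTruth]
    merged_edges: dict[tuple[str, str, str], frozenset]
    node_kinds: dict[str, str]
    nonhuman_genes: set
    human_genes: set
    filtered_edges: dict[tuple[str, str, str], frozenset]
    filtered_node_kinds: dict[str, str]

    def composition(self, filtered: bool = True) -> dict[str, int]:
        kinds = self.filtered_node_kinds if filtered else self.node_kinds
        edges = self.filtered_edges if filtered else self.merged_edges
        counts = {"gene": 0, "chemical": 0, "complex": 0, "intermediate": 0}
        for kind in kinds.values():
            counts[kind] += 1
        return {
            "n_nodes": len(kinds),
            "n_edges": len(edges),
            "n_genes": counts["gene"],
            "n_chemicals": counts["chemical"],
            "n_complexes": counts["complex"],
            "n_intermediates": counts["intermediate"],
        }


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    documents: dict[str, str]
    gene_table: pd.DataFrame
    human_genes: set
    ground_truth: GroundTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for tag in sorted(self.documents):
            path = out_dir / f"{tag}.owl"
            path.write_text(self.documents[tag], encoding="utf-8")
            paths[tag] = path
        gene_path = out_dir / "gene_table.tsv"
        self.gene_table.to_csv(gene_path, sep="\t", index=False)
        paths["gene_table"] = gene_path
        human_path = out_dir / "human_genes.txt"
        human_path.write_text(
            "\n".join(sorted(self.human_genes)) + "\n", encoding="utf-8"
        )
        paths["human_genes"] = human_path
        truth_path = out_dir / "ground_truth.json"
        truth_path.write_text(
            json.dumps(self.ground_truth.composition(), indent=2) + "\n",
            encoding="utf-8",
        )
        paths["ground_truth"] = truth_path
        return paths


# ---------------------------------------------------------------------------
# universe sampling


class _Universe:
    def __init__(self, spec: SyntheticSpec, rng: random.Random):
        self.spec = spec
        self.rng = rng
        self.genes = [f"GENE{i:03d}" for i in range(1, spec.n_genes + 1)]
        self.uniprot = {sym: f"P9{i:04d}" for i, sym in enumerate(self.genes, 1)}
        n_nonhuman = spec.n_databases * max(
            1 if spec.nonhuman_rate > 0 else 0,
            round(spec.nonhuman_rate * spec.reactions_per_db),
        )
        self.nonhuman_genes = [f"XGENE{i:03d}" for i in range(1, n_nonhuman + 1)]
        self.uniprot.update(
            {sym: f"Q8{i:04d}" for i, sym in enumerate(self.nonhuman_genes, 1)}
        )
        self.chem_synonyms: dict[str, dict[str, tuple[str, str]]] = {}
        self.chem_anchor: dict[str, str] = {}
        self.chemicals: list[str] = []  # unified names
        for i in range(1, spec.n_chemicals + 1):
            synonyms = {
                "CID": (f"9{i:04d}9", f"CID9{i:04d}9"),
                "SID": (f"8{i:04d}8", f"SID8{i:04d}8"),
                "CAS": (f"99-{i:04d}-9", f"CAS:99-{i:04d}-9"),
                "KEGG": (f"C9{i:04d}", f"KEGG:C9{i:04d}"),
                "HMDB": (f"HMDB99{i:04d}", f"HMDB99{i:04d}"),
                "ChEBI": (f"9{i:04d}1", f"CHEBI:9{i:04d}1"),
            }
            anchor = rng.choices(_CHEM_SOURCES, weights=(45, 15, 10, 10, 10, 10))[0]
            unified = synonyms[anchor][1]
            key = f"chem{i:03d}"
            self.chem_synonyms[key] = synonyms
            self.chem_anchor[key] = anchor
            self.chemicals.append(key)
        self.used_keys: set = set()
        self.used_names: set = set()
        self.counter = 0
        self.nonhuman_cursor = 0

    def chem_unified(self, key: str) -> str:
        return self.chem_synonyms[key][self.chem_anchor[key]][1]

    def _reserve(self, substrates, controller_names) -> bool:
        key = (frozenset(substrates), frozenset(controller_names))
        name = ";".join(sorted(set(substrates)) + sorted(set(controller_names)))
        if key in self.used_keys or name in self.used_names:
            return False
        self.used_keys.add(key)
        self.used_names.add(name)
        return True

    def _next_id(self) -> str:
        self.counter += 1
        return f"R{self.counter:04d}"

    def _sample_complex(self) -> tuple[str, tuple]:
        rng = self.rng
        members = rng.sample(self.genes, rng.randint(2, 3))
        if len(members) == 3 and rng.random() < 0.4:
            structure: tuple = ((members[0], members[1]), members[2])
        else:
            structure = tuple(members)
        name = "_".join(sorted(set(members)))
        return name, structure

    def sample_reaction(self, nonhuman: bool = False) -> PlantedReaction:
        for _ in range(200):
            reaction = self._draw(nonhuman)
            substrates = set(reaction.substrates)
            controllers = {name for name, _ in reaction.controllers}
            if self._reserve(substrates, controllers):
                return reaction
        raise RuntimeError("could not sample a fresh reaction; universe too small")

    def _draw(self, nonhuman: bool) -> PlantedReaction:
        rng = self.rng
        spec = self.spec
        rid = self._next_id()
        if nonhuman:
            kinase = self.nonhuman_genes[self.nonhuman_cursor % len(self.nonhuman_genes)]
            self.nonhuman_cursor += 1
            substrate = rng.choice(self.genes)
            return PlantedReaction(
                rid=rid, rclass="BiochemicalReaction",
                substrates=(substrate,), products=(substrate,),
                controllers=((kinase, ACTIVATION),), cofactors=(),
                control_class="Catalysis", nonhuman=True,
            )
        if rng.random() < spec.fraction_signaling:
            substrate, kinase = rng.sample(self.genes, 2)
            roll = rng.random()
            if roll < 0.6:
                control_class, sign = "Catalysis", ACTIVATION
            elif roll < 0.85:
                control_class, sign = "Modulation", INHIBITION
            else:
                control_class, sign = "Control", UNKNOWN
            controller: str = kinase
            complexes: dict[str, tuple] = {}
            if rng.random() < spec.complex_rate:
                controller, structure = self._sample_complex()
                complexes[controller] = structure
            return PlantedReaction(
                rid=rid, rclass="BiochemicalReaction",
                substrates=(substrate,), products=(substrate,),
                controllers=((controller, sign),), cofactors=(),
                control_class=control_class, complexes=complexes,
            )
        rclass = rng.choices(
            (
                "BiochemicalReaction", "Transport",
                "TransportWithBiochemicalReaction", "Conversion",
                "Degradation", "ComplexAssembly",
            ),
            weights=(50, 10, 10, 10, 10, 10),
        )[0]
        if rclass == "ComplexAssembly":
            name, structure = self._sample_complex()
            members = tuple(sorted({g for part in structure for g in
                                    (part if isinstance(part, tuple) else (part,))}))
            return PlantedReaction(
                rid=rid, rclass=rclass,
                substrates=members, products=(name,),
                controllers=(), cofactors=(),
                control_class=None, complexes={name: structure},
            )
        if rclass == "Transport":
            chem = self.chem_unified(rng.choice(self.chemicals))
            transporter = rng.choice(self.genes)
            return PlantedReaction(
                rid=rid, rclass=rclass,
                substrates=(chem,), products=(chem,),
                controllers=((transporter, ACTIVATION),), cofactors=(),
                control_class="Catalysis",
            )
        if rclass == "Degradation":
            chem = self.chem_unified(rng.choice(self.chemicals))
            protease = rng.choice(self.genes)
            return PlantedReaction(
                rid=rid, rclass=rclass,
                substrates=(chem,), products=(),
                controllers=((protease, ACTIVATION),), cofactors=(),
                control_class="Catalysis",
            )
        # metabolic conversion
        pool = rng.sample(self.chemicals, 4)
        n_sub = rng.randint(1, 2)
        n_pro = rng.randint(1, 2)
        substrates = tuple(sorted(self.chem_unified(c) for c in pool[:n_sub]))
        products = tuple(sorted(self.chem_unified(c) for c in pool[2 : 2 + n_pro]))
        controllers: tuple[tuple[str, str], ...] = ()
        control_class = None
        complexes = {}
        cofactors: tuple[str, ...] = ()
        if rng.random() < 0.8:
            enzyme = rng.choice(self.genes)
            if rng.random() < spec.complex_rate:
                enzyme, structure = self._sample_complex()
                complexes[enzyme] = structure
            controllers = ((enzyme, ACTIVATION),)
            control_class = "Catalysis"
            if rng.random() < 0.15:
                extra = self.chem_unified(rng.choice(
                    [c for c in self.chemicals if c not in pool]
                ))
                if extra not in substrates and extra not in products:
                    cofactors = (extra,)
        return PlantedReaction(
            rid=rid, rclass=rclass,
            substrates=substrates, products=products,
            controllers=controllers, cofactors=cofactors,
            control_class=control_class, complexes=complexes,
        )


# ---------------------------------------------------------------------------
# OWL materialisation


class _OwlBuilder:
    def __init__(self) -> None:
        nsmap = {"rdf": _RDF, "bp": _BP, "owl": _OWL, "xsd": _XSD}
        self.root = etree.Element(f"{{{_RDF}}}RDF", nsmap=nsmap)
        ontology = etree.SubElement(self.root, f"{{{_OWL}}}Ontology")
        ontology.set(f"{{{_RDF}}}about", "")
        self.seen: set[str] = set()

    def individual(self, biopax_class: str, entity_id: str) -> etree._Element:
        element = etree.SubElement(self.root, f"{{{_BP}}}{biopax_class}")
        element.set(f"{{{_RDF}}}ID", entity_id)
        self.seen.add(entity_id)
        return element

    @staticmethod
    def ref(element: etree._Element, prop: str, target: str) -> None:
        child = etree.SubElement(element, f"{{{_BP}}}{prop}")
        child.set(f"{{{_RDF}}}resource", f"#{target}")

    @staticmethod
    def literal(element: etree._Element, prop: str, value: str) -> None:
        child = etree.SubElement(element, f"{{{_BP}}}{prop}")
        child.set(f"{{{_RDF}}}datatype", f"{_XSD}string")
        child.text = value

    def serialize(self) -> str:
        return etree.tostring(
            self.root, xml_declaration=True, encoding="UTF-8", pretty_print=True
        ).decode("utf-8")


def _materialize_db(
    tag: str,
    reactions: list[PlantedReaction],
    universe: _Universe,
    rng: random.Random,
) -> str:
    builder = _OwlBuilder()
    xref_counter = 0

    def new_xref(xref_class: str, db: str, ext: str) -> str:
        nonlocal xref_counter
        xref_counter += 1
        xid = f"XR{xref_counter:04d}"
        element = builder.individual(xref_class, xid)
        builder.literal(element, "db", db)
        builder.literal(element, "id", ext)
        return xid

    biosources: dict[str, str] = {}

    def biosource(organism: str) -> str:
        if organism not in biosources:
            bid = f"BS{len(biosources) + 1}"
            element = builder.individual("BioSource", bid)
            builder.literal(element, "displayName", organism)
            biosources[organism] = bid
        return biosources[organism]

    protein_ids: dict[str, str] = {}

    def protein(sym: str) -> str:
        if sym in protein_ids:
            return protein_ids[sym]
        organism = NONHUMAN if sym.startswith("XGENE") else HUMAN
        pr_id = f"PR_{sym}"
        reference = builder.individual("ProteinReference", pr_id)
        spelling = rng.choice(_UNIPROT_SPELLINGS)
        builder.ref(reference, "xref", new_xref("UnificationXref", spelling, universe.uniprot[sym]))
        builder.ref(reference, "organism", biosource(organism))
        entity_id = f"PROT_{sym}"
        entity = builder.individual("Protein", entity_id)
        builder.literal(entity, "displayName", f"{sym} protein")
        builder.ref(entity, "entityReference", pr_id)
        if organism == HUMAN and rng.random() < 0.3:
            builder.ref(entity, "xref", new_xref("RelationshipXref", "hgnc symbol", sym))
        protein_ids[sym] = entity_id
        return entity_id

    chem_ids: dict[str, str] = {}

    def chemical_by_unified(unified: str) -> str:
        key = next(
            k for k in universe.chemicals if universe.chem_unified(k) == unified
        )
        if key in chem_ids:
            return chem_ids[key]
        anchor = universe.chem_anchor[key]
        anchor_rank = _CHEM_SOURCES.index(anchor)
        lower = list(_CHEM_SOURCES[anchor_rank + 1 :])
        lo, hi = universe.spec.xref_multiplicity
        n_sources = rng.randint(lo, hi)
        extras = rng.sample(lower, min(max(n_sources - 1, 0), len(lower)))
        smr_id = f"SMR_{key}"
        reference = builder.individual("SmallMoleculeReference", smr_id)
        for source in [anchor] + sorted(extras):
            db_spelling = rng.choice(_DB_SPELLINGS[source])
            ext = universe.chem_synonyms[key][source][0]
            builder.ref(reference, "xref", new_xref("UnificationXref", db_spelling, ext))
        entity_id = f"SM_{key}"
        entity = builder.individual("SmallMolecule", entity_id)
        builder.literal(entity, "displayName", key)
        builder.ref(entity, "entityReference", smr_id)
        chem_ids[key] = entity_id
        return entity_id

    complex_ids: dict[str, str] = {}
    complex_counter = 0

    def complex_entity(name: str, structure: tuple) -> str:
        nonlocal complex_counter
        if name in complex_ids:
            return complex_ids[name]
        complex_counter += 1
        entity_id = f"CPLX{complex_counter:03d}"
        element = builder.individual("Complex", entity_id)
        for part in structure:
            if isinstance(part, tuple):
                complex_counter += 1
                inner_id = f"CPLX{complex_counter:03d}"
                inner = builder.individual("Complex", inner_id)
                for sym in part:
                    builder.ref(inner, "component", protein(sym))
                builder.ref(element, "component", inner_id)
            else:
                builder.ref(element, "component", protein(part))
        complex_ids[name] = entity_id
        return entity_id

    def participant_id(name: str, reaction: PlantedReaction) -> str:
        if name in reaction.complexes:
            return complex_entity(name, reaction.complexes[name])
        if name in complex_ids:
            return complex_ids[name]
        if name.startswith(("GENE", "XGENE")):
            return protein(name)
        if "_" in name and all(
            part.startswith("GENE") for part in name.split("_")
        ):  # complex product named before materialisation
            return complex_entity(name, tuple(name.split("_")))
        return chemical_by_unified(name)

    control_counter = 0
    first_reaction_id: str | None = None
    for reaction in reactions:
        rx_id = f"{tag}_{reaction.rid}"
        if first_reaction_id is None:
            first_reaction_id = rx_id
        element = builder.individual(reaction.rclass, rx_id)
        for name in reaction.substrates:
            builder.ref(element, "left", participant_id(name, reaction))
        for name in reaction.products:
            builder.ref(element, "right", participant_id(name, reaction))
        if reaction.control_class is not None:
            control_counter += 1
            control = builder.individual(
                reaction.control_class, f"CTL{control_counter:04d}"
            )
            for name, sign in reaction.controllers:
                builder.ref(control, "controller", participant_id(name, reaction))
            builder.ref(control, "controlled", rx_id)
            if reaction.control_class == "Modulation":
                builder.literal(control, "controlType", "INHIBITION")
            elif reaction.control_class == "Catalysis" and rng.random() < 0.5:
                builder.literal(control, "controlType", "ACTIVATION")
            for cofactor in reaction.cofactors:
                builder.ref(control, "cofactor", participant_id(cofactor, reaction))

    # distractors: all must be ignored or dropped (and counted) downstream
    empty = builder.individual("BiochemicalReaction", "RX_EMPTY")
    builder.literal(empty, "comment", "no participants; must be dropped")
    template = builder.individual("TemplateReaction", "TMPL1")
    if protein_ids:
        builder.ref(template, "product", next(iter(sorted(protein_ids.values()))))
    if first_reaction_id is not None:
        pathway = builder.individual("Pathway", "PW1")
        builder.literal(pathway, "displayName", f"{tag} synthetic pathway")
        builder.ref(pathway, "pathwayComponent", first_reaction_id)
        if control_counter:
            chained = builder.individual("Control", "CTL_CHAIN")
            builder.ref(chained, "controller", next(iter(sorted(protein_ids.values()))))
            builder.ref(chained, "controlled", "CTL0001")
    return builder.serialize()


# ---------------------------------------------------------------------------
# top-level generation


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate per-database OWL documents, mapping tables and ground truth."""
    spec.validate()
    rng = random.Random(spec.seed)
    universe = _Universe(spec, rng)

    n_shared = round(spec.overlap_fraction * spec.reactions_per_db)
    n_unique = spec.reactions_per_db - n_shared
    n_nonhuman = min(n_unique, round(spec.nonhuman_rate * spec.reactions_per_db))

    shared = [universe.sample_reaction() for _ in range(n_shared)]
    tags = tuple(f"db{i}" for i in range(1, spec.n_databases + 1))
    per_db_reactions: dict[str, list[PlantedReaction]] = {}
    for tag in tags:
        unique = [
            universe.sample_reaction() for _ in range(n_unique - n_nonhuman)
        ] + [universe.sample_reaction(nonhuman=True) for _ in range(n_nonhuman)]
        reactions = shared + unique
        rng.shuffle(reactions)
        per_db_reactions[tag] = reactions

    # --- bookkeeping (plain set logic; the oracle for the pipeline)
    per_db: dict[str, DbTruth] = {}
    merged_edges: dict[tuple[str, str, str], set] = {}
    node_kinds: dict[str, str] = {}
    nonhuman_genes: set = set()
    for tag in tags:
        truth = DbTruth()
        for reaction in per_db_reactions[tag]:
            truth.reactions.append(reaction)
            edges = reaction.edges()
            truth.edges |= edges
            for triple in edges:
                merged_edges.setdefault(triple, set()).add(tag)
            intermediate = reaction.intermediate()
            members = set(reaction.substrates) | {c for c, _ in reaction.controllers}
            if len(members) > 1:
                truth.intermediates.add(intermediate)
                # a single-member intermediate keeps its member's kind (the
                # name is the member), matching the degenerate-case handling
                # of the converter; the participant loop below assigns it
                node_kinds.setdefault(intermediate, "intermediate")
            for name in reaction.complexes:
                truth.complexes.add(name)
                node_kinds[name] = "complex"
            for name in (
                set(reaction.substrates)
                | set(reaction.products)
                | {c for c, _ in reaction.controllers}
                | set(reaction.cofactors)
            ):
                if name in reaction.complexes:
                    continue
                if name.startswith("XGENE"):
                    truth.genes.add(name)
                    node_kinds[name] = "gene"
                    nonhuman_genes.add(name)
                elif name.startswith("GENE"):
                    truth.genes.add(name)
                    node_kinds[name] = "gene"
                else:
                    truth.chemicals.add(name)
                    node_kinds[name] = "chemical"
        per_db[tag] = truth

    filtered_edges = {
        triple: frozenset(dbs)
        for triple, dbs in merged_edges.items()
        if not any(
            token in nonhuman_genes
            for token in (triple[0].split(";") + triple[2].split(";"))
        )
    }
    filtered_nodes = {
        node for source, _, target in filtered_edges for node in (source, target)
    }
    filtered_node_kinds = {
        node: kind for node, kind in node_kinds.items() if node in filtered_nodes
    }

    ground_truth = GroundTruth(
        tags=tags,
        per_db=per_db,
        merged_edges={t: frozenset(dbs) for t, dbs in merged_edges.items()},
        node_kinds=node_kinds,
        nonhuman_genes=nonhuman_genes,
        human_genes=set(universe.genes),
        filtered_edges=filtered_edges,
        filtered_node_kinds=filtered_node_kinds,
    )

    documents = {
        tag: _materialize_db(tag, per_db_reactions[tag], universe, rng)
        for tag in tags
    }

    gene_rows = [
        {
            "source_db": "UniProt",
            "external_id": universe.uniprot[sym],
            "unified_id": sym,
            "kind": "gene",
        }
        for sym in sorted(universe.uniprot)
    ]
    gene_table = pd.DataFrame(gene_rows)

    return SyntheticDataset(
        spec=spec,
        documents=documents,
        gene_table=gene_table,
        human_genes=set(universe.genes),
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# network-level fixtures


def planted_communities(
    n_communities: int = 3,
    n_genes: int = 8,
    n_chemicals: int = 10,
    reactions_per_community: int = 45,
    n_cross: int = 2,
    seed: int = 0,
) -> tuple[GINetwork, dict[str, int]]:
    """Merged network with planted communities: dense intra, sparse inter.

    Each community has its own gene/chemical pools; intra-community reactions
    convert chemicals of the pool under pool enzymes, cross reactions bridge
    consecutive communities.  Returns the merged network and planted labels
    for every unambiguous node (cross-reaction intermediates carry no label).
    """
    rng = random.Random(seed)
    reactions: list[Reaction] = []
    labels: dict[str, int] = {}
    kinds: dict[str, str] = {}
    pools = []
    for community in range(n_communities):
        genes = [f"C{community}GENE{i:02d}" for i in range(n_genes)]
        chems = [f"CID7{community}{i:03d}7" for i in range(n_chemicals)]
        for gene in genes:
            labels[gene] = community
            kinds[gene] = "gene"
        for chem in chems:
            labels[chem] = community
            kinds[chem] = "chemical"
        pools.append((genes, chems))

    counter = 0
    used: set = set()

    def add_reaction(substrates, products, enzyme, community: int | None) -> None:
        nonlocal counter
        key = (frozenset(substrates), enzyme)
        if key in used:
            return
        used.add(key)
        counter += 1
        reaction = Reaction(
            reaction_id=f"PR{counter:04d}",
            reaction_class="BiochemicalReaction",
            substrates=tuple(sorted(substrates)),
            products=tuple(sorted(products)),
            controllers=((enzyme, ACTIVATION),),
            source_db="planted",
        )
        reactions.append(reaction)
        if community is not None:
            name = ";".join(sorted(set(substrates)) + [enzyme])
            labels[name] = community

    for community, (genes, chems) in enumerate(pools):
        for _ in range(reactions_per_community):
            substrates = rng.sample(chems, 2)
            products = rng.sample([c for c in chems if c not in substrates], 2)
            add_reaction(substrates, products, rng.choice(genes), community)
    for bridge in range(n_cross):
        a = bridge % n_communities
        b = (bridge + 1) % n_communities
        substrates = [rng.choice(pools[a][1])]
        products = [rng.choice(pools[b][1])]
        add_reaction(substrates, products, rng.choice(pools[a][0]), None)

    edges, nodes, _ = reactions_to_sifi(reactions, kinds, "planted")
    gin = merge_sifi([("planted", edges, nodes)])
    labels = {node: community for node, community in labels.items() if node in gin.nodes}
    return gin, labels


def glycolysis_like_chain(
    n_steps: int = 10,
    n_regulators: int = 7,
    n_background: int = 6,
    seed: int = 0,
) -> tuple[GINetwork, dict[str, object]]:
    """A linear metabolic chain with planted kinase regulation of its enzymes.

    ``n_steps`` conversions M0 → M1 → ... each catalysed by its own enzyme;
    ``n_regulators`` of those enzymes additionally carry a planted PTM
    reaction (kinase → enzyme, substrate = product) — the structural pattern
    of a metabolic pathway whose steps are controlled by signaling proteins.
    Background reactions on disjoint pools make extraction non-trivial.

    Returns the merged network and a dict with keys ``seeds`` (the chain
    metabolites), ``enzymes``, ``regulators`` and ``regulated_enzymes``.
    """
    rng = random.Random(seed)
    metabolites = [f"CID55{i:03d}5" for i in range(n_steps + 1)]
    enzymes = [f"ENZ{i:02d}" for i in range(n_steps)]
    regulated = sorted(rng.sample(range(n_steps), n_regulators))
    regulators = [f"KIN{i:02d}" for i in range(n_regulators)]

    kinds = {m: "chemical" for m in metabolites}
    kinds.update({e: "gene" for e in enzymes})
    kinds.update({k: "gene" for k in regulators})

    reactions = [
        Reaction(
            reaction_id=f"STEP{i:02d}",
            reaction_class="BiochemicalReaction",
            substrates=(metabolites[i],),
            products=(metabolites[i + 1],),
            controllers=((enzymes[i], ACTIVATION),),
            source_db="core",
        )
        for i in range(n_steps)
    ]
    for kinase, step in zip(regulators, regulated):
        enzyme = enzymes[step]
        reactions.append(
            Reaction(
                reaction_id=f"PTM_{kinase}",
                reaction_class="BiochemicalReaction",
                substrates=(enzyme,),
                products=(enzyme,),
                controllers=((kinase, ACTIVATION),),
                source_db="ptm",
            )
        )
    for i in range(n_background):
        substrate = f"CID66{i:03d}6"
        product = f"CID66{i:03d}7"
        gene = f"BGGENE{i:02d}"
        kinds.update({substrate: "chemical", product: "chemical", gene: "gene"})
        reactions.append(
            Reaction(
                reaction_id=f"BG{i:02d}",
                reaction_class="BiochemicalReaction",
                substrates=(substrate,),
                products=(product,),
                controllers=((gene, ACTIVATION),),
                source_db="background",
            )
        )

    edges, nodes, _ = reactions_to_sifi(reactions, kinds, "planted")
    gin = merge_sifi([("planted", edges, nodes)])
    info = {
        "seeds": list(metabolites),
        "enzymes": list(enzymes),
        "regulators": list(regulators),
        "regulated_enzymes": [enzymes[i] for i in regulated],
    }
    return gin, info
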