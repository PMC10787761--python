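"""Parse BioPAX level-3 OWL (RDF/XML) documents into flat entity tables.

BioPAX level 3 stores pathway knowledge as RDF individuals (proteins, small
molecules, complexes, reactions, controls, ...) whose typed properties
(``left``, ``right``, ``controller``, ``component``, ``xref`` ...) reference
other individuals or carry literals.  This module flattens one document into
:class:`EntityRecord` objects — one per individual, property order preserved
as written — and derives the internal→external cross-reference table used for
identifier unification.

Only the BioPAX level-3 vocabulary is interpreted; RDF elements from other
namespaces are counted and ignored.  Internal entity IDs are the URI fragment
after ``#`` (the full URI when there is no fragment), matching the convention
of PathwayCommons exports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

BIOPAX_NS = "http://www.biopax.org/release/biopax-level3.owl#"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"

_RDF_ID = f"{{{RDF_NS}}}ID"
_RDF_ABOUT = f"{{{RDF_NS}}}about"
_RDF_RESOURCE = f"{{{RDF_NS}}}resource"

#: BioPAX level-3 classes we expect to see; anything else in the BioPAX
#: namespace is kept verbatim with a warning (never dropped silently).
KNOWN_CLASSES = frozenset(
    {
        "BindingFeature", "BiochemicalPathwayStep", "BiochemicalReaction",
        "BioSource", "Catalysis", "CellularLocationVocabulary",
        "CellVocabulary", "ChemicalStructure", "Complex", "ComplexAssembly",
        "Control", "Conversion", "Degradation", "DeltaG", "Dna", "DnaRegion",
        "DnaRegionReference", "DnaReference", "EntityFeature",
        "EntityReferenceTypeVocabulary", "Evidence", "EvidenceCodeVocabulary",
        "ExperimentalForm", "ExperimentalFormVocabulary", "FragmentFeature",
        "Gene", "GeneticInteraction", "Interaction",
        "InteractionVocabulary", "KPrime", "ModificationFeature", "Modulation",
        "MolecularInteraction", "Pathway", "PathwayStep", "PhenotypeVocabulary",
        "PhysicalEntity", "Protein", "ProteinReference", "Provenance",
        "PublicationXref", "RelationshipTypeVocabulary", "RelationshipXref",
        "Rna", "RnaRegion", "RnaRegionReference", "RnaReference", "Score",
        "SequenceInterval", "SequenceLocation", "SequenceModificationVocabulary",
        "SequenceRegionVocabulary", "SequenceSite", "SmallMolecule",
        "SmallMoleculeReference", "Stoichiometry", "TemplateReaction",
        "TemplateReactionRegulation", "TissueVocabulary", "Transport",
        "TransportWithBiochemicalReaction", "UnificationXref",
    }
)

#: Classes whose xrefs feed the ID-mapping table (directly or through their
#: entityReference).
PHYSICAL_ENTITY_CLASSES = frozenset(
    {
        "PhysicalEntity", "Protein", "SmallMolecule", "Complex",
        "Dna", "DnaRegion", "Rna", "RnaRegion", "Gene",
    }
)

#: Default normalisation of xref ``db`` spellings to canonical source names.
#: Case-folded keys; anything not listed is kept case-folded as-is.  The six
#: unified-chemical-ID sources map to CID / SID / CAS / KEGG / HMDB / ChEBI.
DEFAULT_SOURCE_ALIASES: Mapping[str, str] = {
    "pubchem": "CID",
    "pubchem compound": "CID",
    "pubchem-compound": "CID",
    "pubchem.compound": "CID",
    "cid": "CID",
    "pubchem substance": "SID",
    "pubchem-substance": "SID",
    "pubchem.substance": "SID",
    "sid": "SID",
    "cas": "CAS",
    "cas registry number": "CAS",
    "chebi": "ChEBI",
    "hmdb": "HMDB",
    "kegg": "KEGG",
    "kegg compound": "KEGG",
    "kegg.compound": "KEGG",
    "ligand": "KEGG",
    "uniprot": "UniProt",
    "uniprotkb": "UniProt",
    "uniprot knowledgebase": "UniProt",
    "uniprot isoform": "UniProt",
    "swissprot": "UniProt",
    "hgnc": "HGNC Symbol",
    "hgnc symbol": "HGNC Symbol",
    "hgnc.symbol": "HGNC Symbol",
}


@dataclass
class EntityRecord:
    """One BioPAX individual: class, optional display name, ordered properties.

    ``properties`` maps property name → list of values in document order;
    values are entity IDs (for resource references) or verbatim literals.
    """

    entity_id: str
    biopax_class: str
    display_name: str | None = None
    properties: dict[str, list[str]] = field(default_factory=dict)

    def prop(self, name: str) -> list[str]:
        return self.properties.get(name, [])

    def first(self, name: str) -> str | None:
        values = self.properties.get(name)
        return values[0] if values else None


class XRefEntry(NamedTuple):
    """One internal→external identifier link."""

    entity_id: str
    source_db: str
    external_id: str


def _local_id(uri: str) -> str:
    """URI fragment after '#', or the full URI when there is no fragment."""
    if "#" in uri:
        return uri.rsplit("#", 1)[1]
    return uri


def parse_biopax(owl_document: str | bytes) -> list[EntityRecord]:
    """Parse one BioPAX level-3 RDF/XML document into entity records.

    Property order and literal values are preserved exactly as written.
    Anonymous nested individuals are registered under synthesised
    ``_anon<N>`` IDs.  Malformed XML raises :class:`lxml.etree.XMLSyntaxError`
    (the message names the offending line); unknown BioPAX classes are kept
    with a logged warning.
    """
    if isinstance(owl_document, str):
        owl_document = owl_document.encode("utf-8")
    root = etree.fromstring(owl_document)

    records: list[EntityRecord] = []
    ignored_foreign = 0
    anon_counter = 0

    def register(element: etree._Element) -> str:
        """Register one individual element; returns its entity id."""
        nonlocal anon_counter
        qname = etree.QName(element)
        biopax_class = qname.localname
        if element.get(_RDF_ID) is not None:
            entity_id = element.get(_RDF_ID)
        elif element.get(_RDF_ABOUT) is not None:
            entity_id = _local_id(element.get(_RDF_ABOUT))
        else:
            anon_counter += 1
            entity_id = f"_anon{anon_counter}"
        if biopax_class not in KNOWN_CLASSES:
            logger.warning(
                "unknown BioPAX class %r for entity %r (kept as-is)",
                biopax_class, entity_id,
            )
        record = EntityRecord(entity_id=entity_id, biopax_class=biopax_class)
        for child in element:
            if not isinstance(child.tag, str):
                continue  # comments / PIs
            pname = etree.QName(child).localname
            resource = child.get(_RDF_RESOURCE)
            if resource is not None:
                value = _local_id(resource)
            else:
                inline = [g for g in child if isinstance(g.tag, str)]
                if inline:
                    # inline (possibly anonymous) individual
                    value = register(inline[0])
                else:
                    value = child.text if child.text is not None else ""
            record.properties.setdefault(pname, []).append(value)
        record.display_name = (
            record.first("displayName")
            or record.first("standardName")
            or record.first("name")
        )
        records.append(record)
        return entity_id

    for element in root:
        if not isinstance(element.tag, str):
            continue
        if etree.QName(element).namespace != BIOPAX_NS:
            ignored_foreign += 1
            continue
        register(element)

    if ignored_foreign:
        logger.info("ignored %d non-BioPAX top-level RDF elements", ignored_foreign)
    return records


def dangling_references(entities: Iterable[EntityRecord]) -> set[str]:
    """IDs referenced in properties that resolve to no entity in the document.

    Literal property values are not references and are never flagged; a value
    is only checked when its property conventionally holds object references.
    """
    by_id = {e.entity_id for e in entities}
    reference_props = {
        "left", "right", "product", "controller", "controlled", "cofactor",
        "component", "xref", "entityReference", "organism", "memberPhysicalEntity",
        "memberEntityReference", "pathwayComponent", "participant",
    }
    dangling: set[str] = set()
    for entity in entities:
        for pname, values in entity.properties.items():
            if pname not in reference_props:
                continue
            for value in values:
                if value not in by_id:
                    dangling.add(value)
    return dangling


def normalize_source_db(
    raw: str, aliases: Mapping[str, str] = DEFAULT_SOURCE_ALIASES
) -> str:
    """Case-fold an xref ``db`` string and apply the alias table."""
    folded = raw.strip().casefold()
    return aliases.get(folded, folded)


def build_xref_table(
    entities: Iterable[EntityRecord],
    aliases: Mapping[str, str] = DEFAULT_SOURCE_ALIASES,
    diag=None,
) -> list[XRefEntry]:
    """Collect every xref reachable from a physical entity.

    Xrefs attached to an entity's ``entityReference`` (ProteinReference,
    SmallMoleculeReference, ...) are inherited by the entity itself — real
    PathwayCommons exports attach almost all unification xrefs there.  Xrefs
    with a missing ``db`` or ``id`` field are skipped and counted.  The
    result is sorted, deduplicated, and independent of entity order.
    """
    entities = list(entities)
    by_id = {e.entity_id: e for e in entities}
    entries: set[XRefEntry] = set()
    skipped = 0

    def xref_targets(entity: EntityRecord) -> list[EntityRecord]:
        targets = []
        for xref_id in entity.prop("xref"):
            target = by_id.get(xref_id)
            if target is not None:
                targets.append(target)
        return targets

    for entity in entities:
        if entity.biopax_class not in PHYSICAL_ENTITY_CLASSES:
            continue
        xrefs = xref_targets(entity)
        for ref_id in entity.prop("entityReference"):
            reference = by_id.get(ref_id)
            if reference is not None:
                xrefs.extend(xref_targets(reference))
        for xref in xrefs:
            db = xref.first("db")
            ext = xref.first("id")
            if not db or not ext:
                skipped += 1
                continue
            entries.add(XRefEntry(entity.entity_id, normalize_source_db(db, aliases), ext))

    if diag is not None and skipped:
        diag.count("xref_missing_db_or_id", skipped)
    if skipped:
        logger.info("skipped %d xrefs with missing db or id", skipped)
    return sorted(entries)


def entities_to_frame(entities: Iterable[EntityRecord]) -> pd.DataFrame:
    """Long-format entity table: one row per (entity, property, value).

    Entities without properties still contribute one row (empty property) so
    that no individual is lost on re-serialisation.
    """
    rows = []
    for entity in entities:
        emitted = False
        for pname, values in entity.properties.items():
            for value in values:
                rows.append(
                    (entity.entity_id, entity.biopax_class, entity.display_name or "", pname, value)
                )
                emitted = True
        if not emitted:
            rows.append((entity.entity_id, entity.biopax_class, entity.display_name or "", "", ""))
    return pd.DataFrame(
        rows, columns=["entity_id", "biopax_class", "display_name", "property", "value"]
    )


def xrefs_to_frame(xrefs: Iterable[XRefEntry]) -> pd.DataFrame:
    return pd.DataFrame(xrefs, columns=["entity_id", "source_db", "external_id"])


def write_entity_tables(entities, xrefs, out_prefix: str) -> tuple[str, str]:
    """Write UTF-8 TSV tables ``<prefix>.entities.tsv`` / ``<prefix>.xrefs.tsv``."""
    entity_path = f"{out_prefix}.entities.tsv"
    xref_path = f"{out_prefix}.xrefs.tsv"
    entities_to_frame(entities).to_csv(entity_path, sep="\t", index=False)
    xrefs_to_frame(xrefs).to_csv(xref_path, sep="\t", index=False)
    return entity_path, xref_path


def load_alias_table(path: str) -> dict[str, str]:
    """Read a two-column TSV (raw spelling, canonical source) alias table."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    raw_col, canon_col = frame.columns[:2]
    return {
        str(row[raw_col]).strip().casefold(): str(row[canon_col])
        for _, row in frame.iterrows()
    }
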