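"""Unify internal entity IDs into gene symbols and unified chemical IDs.

Each knowledge base refers to the same molecule through its own internal IDs
linked to external identifiers from dozens of sources.  Integration requires
one name per molecule across all databases:

* genes/proteins → gene symbols, via a direct HGNC-symbol xref when present,
  else a (source, external_id) → symbol mapping table (file-driven, no
  network calls; UniProt accessions are the usual route);
* small molecules → unified chemical IDs (UC_IDs) in one of six types — CID,
  SID, CAS, KEGG, HMDB, ChEBI — picked by a configurable precedence over the
  sources available for that molecule.  The type is recoverable from the ID
  string (``CID…``, ``SID…``, ``CAS:…``, ``KEGG:…``, ``HMDB…``, ``CHEBI:…``).

Entities that are neither protein/gene nor small molecule fall back to their
display name under a ``NAME:`` prefix so nothing is lost silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .biopax_io import EntityRecord, XRefEntry, normalize_source_db
from .diagnostics import Diagnostics
from .reaction_extract import Reaction

logger = logging.getLogger(__name__)

GENE = "gene"
CHEMICAL = "chemical"

#: Default precedence over unified-chemical-ID source types.
DEFAULT_CHEMICAL_PRECEDENCE: tuple[str, ...] = (
    "CID", "SID", "CAS", "KEGG", "HMDB", "ChEBI",
)

#: How each UC_ID type prefixes its identifier string.
_CHEMICAL_PREFIX: Mapping[str, str] = {
    "CID": "CID",
    "SID": "SID",
    "CAS": "CAS:",
    "KEGG": "KEGG:",
    "HMDB": "HMDB",
    "ChEBI": "CHEBI:",
}

_GENE_CLASSES = frozenset({"Protein", "Gene"})
_CHEMICAL_CLASSES = frozenset({"SmallMolecule"})


@dataclass
class IDMap:
    """entity_id → (unified_id, kind) plus the chemical source precedence."""

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)
    precedence: tuple[str, ...] = DEFAULT_CHEMICAL_PRECEDENCE

    def unified(self, entity_id: str) -> str | None:
        entry = self.entries.get(entity_id)
        return entry[0] if entry else None

    def kind(self, entity_id: str) -> str | None:
        entry = self.entries.get(entity_id)
        return entry[1] if entry else None

    def unified_kinds(self) -> dict[str, str]:
        """unified name → kind; inconsistent duplicate kinds are an error."""
        kinds: dict[str, str] = {}
        for unified_id, kind in self.entries.values():
            previous = kinds.setdefault(unified_id, kind)
            if previous != kind:
                raise ValueError(
                    f"unified id {unified_id!r} maps to both kinds "
                    f"{previous!r} and {kind!r}"
                )
        return kinds


def format_chemical_id(source: str, external_id: str) -> str:
    """Attach the type-recoverable prefix, tolerating already-prefixed IDs."""
    prefix = _CHEMICAL_PREFIX[source]
    bare = external_id.strip()
    if bare.upper().startswith(prefix.upper()):
        bare = bare[len(prefix):]
    return f"{prefix}{bare}"


class GeneSymbolTable:
    """(source_db, external_id) → gene symbol, loaded from a TSV file."""

    def __init__(self, entries: Mapping[tuple[str, str], str] | None = None):
        self.entries: dict[tuple[str, str], str] = {
            (normalize_source_db(source), external_id): symbol
            for (source, external_id), symbol in (entries or {}).items()
        }

    @classmethod
    def from_tsv(cls, path: str) -> "GeneSymbolTable":
        """Columns (source_db, external_id, unified_id[, kind]); extra columns ignored."""
        frame = pd.read_csv(path, sep="\t", dtype=str)
        entries = {
            (str(row.iloc[0]), str(row.iloc[1])): str(row.iloc[2])
            for _, row in frame.iterrows()
        }
        return cls(entries)

    def lookup(self, source_db: str, external_id: str) -> str | None:
        return self.entries.get((normalize_source_db(source_db), external_id))


def unify_gene_id(
    entity_id: str,
    xrefs: Sequence[XRefEntry],
    gene_table: GeneSymbolTable,
    diag: Diagnostics | None = None,
) -> str:
    """Resolve one protein/gene entity to a gene symbol.

    Priority when several xrefs disagree: a direct HGNC-symbol xref (the
    external_id *is* the symbol) beats a UniProt table mapping, which beats
    mappings from any other source; remaining ties break on sorted
    (source, external_id).  Conflicts are logged and counted, never fatal.
    With no mappable xref the placeholder ``UNMAPPED:<entity_id>`` is
    returned and counted.
    """
    candidates: list[tuple[int, str, str, str]] = []
    for xref in sorted(xrefs):
        if xref.source_db == "HGNC Symbol":
            candidates.append((0, xref.source_db, xref.external_id, xref.external_id))
            continue
        symbol = gene_table.lookup(xref.source_db, xref.external_id)
        if symbol is None:
            continue
        rank = 1 if xref.source_db == "UniProt" else 2
        candidates.append((rank, xref.source_db, xref.external_id, symbol))

    if not candidates:
        if diag is not None:
            diag.count("genes_unmapped")
        return f"UNMAPPED:{entity_id}"

    candidates.sort()
    symbols = {symbol for *_, symbol in candidates}
    if len(symbols) > 1:
        if diag is not None:
            diag.count("gene_symbol_conflicts")
        logger.info(
            "entity %s maps to several symbols %s; keeping %s by priority",
            entity_id, sorted(symbols), candidates[0][3],
        )
    return candidates[0][3]


def unify_chemical_id(
    entity_id: str,
    xrefs: Sequence[XRefEntry],
    precedence: Sequence[str] = DEFAULT_CHEMICAL_PRECEDENCE,
    display_name: str | None = None,
    diag: Diagnostics | None = None,
) -> str:
    """Resolve one small molecule to a unified chemical ID.

    The highest-precedence source type with at least one xref supplies the
    ID; ties within a type break on the lexicographically smallest external
    ID.  Without any xref in the six types the display name is used under a
    ``NAME:`` prefix and counted.
    """
    by_source: dict[str, list[str]] = {}
    for xref in xrefs:
        if xref.source_db in _CHEMICAL_PREFIX:
            by_source.setdefault(xref.source_db, []).append(xref.external_id)
    for source in precedence:
        if source in by_source:
            return format_chemical_id(source, min(by_source[source]))
    if diag is not None:
        diag.count("chemicals_without_ucid_xref")
    fallback = display_name if display_name else entity_id
    return f"NAME:{fallback}"


def build_id_map(
    entities: Sequence[EntityRecord],
    xrefs: Iterable[XRefEntry],
    gene_table: GeneSymbolTable,
    precedence: Sequence[str] = DEFAULT_CHEMICAL_PRECEDENCE,
    diag: Diagnostics | None = None,
) -> IDMap:
    """Unify every non-complex physical entity in one document.

    Proteins and genes become symbols; small molecules become UC_IDs; other
    physical entities (RNA, DNA regions, generic physical entities) fall back
    to ``NAME:<display name>`` and are treated as gene-side nodes.  Complexes
    are left to the complex resolver.
    """
    xrefs_by_entity: dict[str, list[XRefEntry]] = {}
    for xref in xrefs:
        xrefs_by_entity.setdefault(xref.entity_id, []).append(xref)

    id_map = IDMap(precedence=tuple(precedence))
    for entity in entities:
        entity_xrefs = xrefs_by_entity.get(entity.entity_id, [])
        if entity.biopax_class in _GENE_CLASSES:
            unified = unify_gene_id(entity.entity_id, entity_xrefs, gene_table, diag)
            id_map.entries[entity.entity_id] = (unified, GENE)
        elif entity.biopax_class in _CHEMICAL_CLASSES:
            unified = unify_chemical_id(
                entity.entity_id, entity_xrefs, precedence, entity.display_name, diag
            )
            id_map.entries[entity.entity_id] = (unified, CHEMICAL)
        elif entity.biopax_class in {"Rna", "RnaRegion", "Dna", "DnaRegion", "PhysicalEntity"}:
            fallback = entity.display_name or entity.entity_id
            id_map.entries[entity.entity_id] = (f"NAME:{fallback}", GENE)
            if diag is not None:
                diag.count("entities_unified_by_name")
    return id_map


def apply_id_map(
    reactions: Sequence[Reaction], id_map: IDMap
) -> list[Reaction]:
    """Replace reaction participants by their unified names.

    Names without a map entry (already-unified names, complex canonical
    names, UNMAPPED placeholders) pass through unchanged, which makes the
    operation idempotent.  Reaction count and per-reaction participant
    counts are preserved (participants are sets before and after).
    """

    def rename(name: str) -> str:
        unified = id_map.unified(name)
        return unified if unified is not None else name

    unified_reactions = []
    for reaction in reactions:
        unified_reactions.append(
            replace(
                reaction,
                substrates=tuple(sorted({rename(s) for s in reaction.substrates})),
                products=tuple(sorted({rename(p) for p in reaction.products})),
                controllers=tuple(
                    sorted({(rename(c), sign) for c, sign in reaction.controllers})
                ),
                cofactors=tuple(sorted({rename(c) for c in reaction.cofactors})),
            )
        )
    return unified_reactions
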