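"""End-to-end orchestration: OWL documents in, GIN and analyses out.

One database is converted by chaining the stage modules: parse → xref table
→ reaction extraction → controller linking → identifier unification →
complex resolution → SIFI conversion.  The run-level driver converts every
tagged input, merges, applies the non-human filter, and writes the consensus
and network-analysis artifacts, with a diagnostics report reconciling what
went in against what came out.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import (
    biopax_io,
    complex_resolver,
    consensus,
    id_unify,
    merge as merge_mod,
    netanalysis,
    reaction_extract,
    sifi_core,
)
from .diagnostics import Diagnostics
from .id_unify import DEFAULT_CHEMICAL_PRECEDENCE, GeneSymbolTable
from .merge import GINetwork
from .sifi_core import NodeAttr, SIFIEdge

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Run-level knobs; all randomness (Leiden only) is seeded from here."""

    chemical_precedence: tuple[str, ...] = DEFAULT_CHEMICAL_PRECEDENCE
    expand_reversible: bool = False
    leiden_resolution: float = 1.0
    leiden_seed: int = 0
    human_gene_table: str | None = None
    source_alias_table: str | None = None
    human_organism: str = "Homo sapiens"

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        if path.endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text) or {}
        else:
            raw = json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "chemical_precedence" in raw:
            raw["chemical_precedence"] = tuple(raw["chemical_precedence"])
        return cls(**raw)

    def validate(self) -> None:
        missing = set(DEFAULT_CHEMICAL_PRECEDENCE) - set(self.chemical_precedence)
        if missing:
            raise ValueError(
                f"chemical_precedence must cover all six UC_ID types; missing {sorted(missing)}"
            )
        for attr in ("human_gene_table", "source_alias_table"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{attr}: no such file {path!r}")


@dataclass
class ConvertResult:
    tag: str
    edges: list[SIFIEdge]
    nodes: dict[str, NodeAttr]
    nonhuman_genes: set[str]
    diagnostics: Diagnostics = field(default_factory=Diagnostics)


def collect_nonhuman_genes(
    entities: Sequence[biopax_io.EntityRecord],
    id_map: id_unify.IDMap,
    human_organism: str,
) -> set[str]:
    """Unified symbols of gene entities annotated with a non-human organism.

    Follows Protein → entityReference → organism → BioSource displayName.
    """
    by_id = {e.entity_id: e for e in entities}
    nonhuman: set[str] = set()
    for entity in entities:
        if id_map.kind(entity.entity_id) != id_unify.GENE:
            continue
        organisms = list(entity.prop("organism"))
        for ref_id in entity.prop("entityReference"):
            reference = by_id.get(ref_id)
            if reference is not None:
                organisms.extend(reference.prop("organism"))
        for organism_id in organisms:
            source = by_id.get(organism_id)
            name = source.display_name if source is not None else None
            if name and name != human_organism:
                nonhuman.add(id_map.unified(entity.entity_id))
    return nonhuman


def convert_document(
    owl_text: str | bytes,
    tag: str,
    gene_table: GeneSymbolTable,
    config: RunConfig | None = None,
) -> ConvertResult:
    """Full conversion of one BioPAX document to tagged SIFI edges."""
    config = config or RunConfig()
    aliases = (
        biopax_io.load_alias_table(config.source_alias_table)
        if config.source_alias_table
        else biopax_io.DEFAULT_SOURCE_ALIASES
    )
    diag = Diagnostics()

    entities = biopax_io.parse_biopax(owl_text)
    diag.count("entities_parsed", len(entities))
    xrefs = biopax_io.build_xref_table(entities, aliases, diag)

    reactions = reaction_extract.extract_reactions(
        entities, tag, expand_reversible=config.expand_reversible, diag=diag
    )
    reactions = reaction_extract.attach_controls(entities, reactions, diag)

    id_map = id_unify.build_id_map(
        entities, xrefs, gene_table, config.chemical_precedence, diag
    )
    nonhuman = collect_nonhuman_genes(entities, id_map, config.human_organism)

    resolutions = complex_resolver.resolve_all_complexes(entities, id_map, diag)
    complex_ids = frozenset(
        e.entity_id for e in entities if e.biopax_class == "Complex"
    )
    reactions = complex_resolver.rewrite_complex_ids(reactions, resolutions, complex_ids)
    reactions = id_unify.apply_id_map(reactions, id_map)

    node_kinds = id_map.unified_kinds()
    node_kinds.update(
        {res.canonical_name: sifi_core.COMPLEX for res in resolutions.values()}
    )
    edges, nodes, _ = sifi_core.reactions_to_sifi(reactions, node_kinds, tag, diag)
    return ConvertResult(
        tag=tag, edges=edges, nodes=nodes, nonhuman_genes=nonhuman, diagnostics=diag
    )


def load_human_genes(path: str) -> set[str]:
    """One symbol per line (a plain list, or first column of a TSV)."""
    symbols = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            symbols.add(line.split("\t")[0])
    return symbols


def run_pipeline(
    config: RunConfig,
    inputs: Sequence[tuple[str, str | Path]],
    out_dir: str | Path,
    gene_table: GeneSymbolTable | None = None,
    human_genes: set[str] | None = None,
) -> dict:
    """Convert, merge, filter and analyse a set of tagged OWL files.

    Writes per-database SIFI files, the merged and human-filtered GIN,
    consensus tables, degree/cluster/composition/contribution tables, and a
    ``diagnostics.json`` reconciling dropped/removed items.  Returns the key
    in-memory results.
    """
    config.validate()
    if gene_table is None:
        raise ValueError("a gene symbol table is required (gene_table=...)")
    if human_genes is None:
        if config.human_gene_table is None:
            raise ValueError("human gene table required (config.human_gene_table)")
        human_genes = load_human_genes(config.human_gene_table)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    run_diag = Diagnostics()

    converted: list[ConvertResult] = []
    for tag, path in inputs:
        result = convert_document(Path(path).read_bytes(), tag, gene_table, config)
        converted.append(result)
        sifi_core.write_sifi(result.edges, result.nodes, out_dir / f"{tag}.sifi")
        run_diag.merge(result.diagnostics)

    gin = merge_mod.merge_sifi(
        [(r.tag, r.edges, r.nodes) for r in converted], run_diag
    )
    known_nonhuman = set().union(*(r.nonhuman_genes for r in converted)) if converted else set()
    filtered = merge_mod.filter_nonhuman(gin, human_genes, known_nonhuman, run_diag)
    sifi_core.write_sifi(filtered.edge_list(), filtered.nodes, out_dir / "gin.sifi")
    sifi_core.export_sif(filtered.edge_list(), out_dir / "gin.sif")

    # consensus over per-database element sets
    per_db_genes = {
        r.tag: {n for n, a in r.nodes.items() if a.kind == sifi_core.GENE}
        for r in converted
    }
    per_db_chems = {
        r.tag: {n for n, a in r.nodes.items() if a.kind == sifi_core.CHEMICAL}
        for r in converted
    }
    per_db_edges = {
        r.tag: {e.triple() for e in r.edges} for r in converted
    }
    overlaps = {
        "gene": consensus.overlap_analysis(per_db_genes, "gene"),
        "chemical": consensus.overlap_analysis(per_db_chems, "chemical"),
        "edge": consensus.overlap_analysis(per_db_edges, "edge"),
    }
    for kind, table in overlaps.items():
        consensus.write_overlap_table(table, out_dir / f"overlap_{kind}.tsv")
        consensus.uniqueness_stats(table).to_csv(
            out_dir / f"uniqueness_{kind}.tsv", sep="\t"
        )

    degree = netanalysis.degree_table(filtered, top_k=20)
    degree.to_csv(out_dir / "degree_top20.tsv", sep="\t", index=False)
    partition = netanalysis.cluster_leiden(
        filtered, resolution=config.leiden_resolution, seed=config.leiden_seed
    )
    composition = netanalysis.cluster_composition(filtered, partition, top_n=20)
    composition.to_csv(out_dir / "cluster_composition.tsv", sep="\t", index=False)
    contribution_pct, contribution_log = netanalysis.db_contribution(filtered, partition)
    contribution_pct.to_csv(out_dir / "db_contribution_pct.tsv", sep="\t")
    contribution_log.to_csv(out_dir / "db_contribution_log10.tsv", sep="\t")

    (out_dir / "diagnostics.json").write_text(
        json.dumps(run_diag.as_dict(), indent=2) + "\n", encoding="utf-8"
    )
    return {
        "converted": converted,
        "gin": gin,
        "filtered": filtered,
        "overlaps": overlaps,
        "degree": degree,
        "partition": partition,
        "composition": composition,
        "contribution_pct": contribution_pct,
        "diagnostics": run_diag,
    }
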