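"""Shared fixtures: a tiny hand-written BioPAX document and the synthetic
multi-database corpus (generated in-memory; nothing is downloaded)."""

from __future__ import annotations

import pytest

from ginkit.id_unify import GeneSymbolTable
from ginkit.pipeline import RunConfig, run_pipeline
from ginkit.synthetic import SyntheticSpec, generate

# One reaction CIDa + CIDb --[ENZ]--> CIDc, a complex of two proteins, and
# xrefs covering UniProt / ChEBI / PubChem.  Hand-written so parser tests
# do not depend on the generator.
TINY_OWL = """<?xml version="1.0" encoding="UTF-8"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:bp="http://www.biopax.org/release/biopax-level3.owl#"
         xmlns:owl="http://www.w3.org/2002/07/owl#"
         xmlns:xsd="http://www.w3.org/2001/XMLSchema#">
  <owl:Ontology rdf:about=""/>
  <bp:UnificationXref rdf:ID="xref_up">
    <bp:db rdf:datatype="http://www.w3.org/2001/XMLSchema#string">UniProt</bp:db>
    <bp:id rdf:datatype="http://www.w3.org/2001/XMLSchema#string">P_FIX1</bp:id>
  </bp:UnificationXref>
  <bp:UnificationXref rdf:ID="xref_chebi">
    <bp:db rdf:datatype="http://www.w3.org/2001/XMLSchema#string">ChEBI</bp:db>
    <bp:id rdf:datatype="http://www.w3.org/2001/XMLSchema#string">15422</bp:id>
  </bp:UnificationXref>
  <bp:UnificationXref rdf:ID="xref_cid">
    <bp:db rdf:datatype="http://www.w3.org/2001/XMLSchema#string">PubChem-compound</bp:db>
    <bp:id rdf:datatype="http://www.w3.org/2001/XMLSchema#string">5957</bp:id>
  </bp:UnificationXref>
  <bp:UnificationXref rdf:ID="xref_kegg">
    <bp:db rdf:datatype="http://www.w3.org/2001/XMLSchema#string">KEGG Compound</bp:db>
    <bp:id rdf:datatype="http://www.w3.org/2001/XMLSchema#string">C00031</bp:id>
  </bp:UnificationXref>
  <bp:ProteinReference rdf:ID="pref_enz">
    <bp:xref rdf:resource="#xref_up"/>
  </bp:ProteinReference>
  <bp:Protein rdf:ID="prot_enz">
    <bp:displayName rdf:datatype="http://www.w3.org/2001/XMLSchema#string">enzyme one</bp:displayName>
    <bp:entityReference rdf:resource="#pref_enz"/>
  </bp:Protein>
  <bp:Protein rdf:ID="prot_b">
    <bp:displayName rdf:datatype="http://www.w3.org/2001/XMLSchema#string">subunit B</bp:displayName>
  </bp:Protein>
  <bp:SmallMolecule rdf:ID="sm_atp">
    <bp:displayName rdf:datatype="http://www.w3.org/2001/XMLSchema#string">ATP</bp:displayName>
    <bp:xref rdf:resource="#xref_chebi"/>
    <bp:xref rdf:resource="#xref_cid"/>
  </bp:SmallMolecule>
  <bp:SmallMolecule rdf:ID="sm_glc">
    <bp:displayName rdf:datatype="http://www.w3.org/2001/XMLSchema#string">glucose</bp:displayName>
    <bp:xref rdf:resource="#xref_kegg"/>
  </bp:SmallMolecule>
  <bp:Complex rdf:ID="cplx1">
    <bp:component rdf:resource="#prot_enz"/>
    <bp:component rdf:resource="#prot_b"/>
  </bp:Complex>
  <bp:BiochemicalReaction rdf:ID="rxn1">
    <bp:left rdf:resource="#sm_atp"/>
    <bp:left rdf:resource="#sm_glc"/>
    <bp:right rdf:resource="#sm_atp"/>
  </bp:BiochemicalReaction>
  <bp:Catalysis rdf:ID="cat1">
    <bp:controller rdf:resource="#prot_enz"/>
    <bp:controlled rdf:resource="#rxn1"/>
  </bp:Catalysis>
</rdf:RDF>
"""

#: The desk-scale study conditions: three databases, 50 reactions each,
#: a fifth of the reactions planted into every database, fixed seed.
STUDY_SPEC = SyntheticSpec(
    n_databases=3, reactions_per_db=50, overlap_fraction=0.2, seed=7
)


@pytest.fixture
def tiny_owl() -> str:
    return TINY_OWL


@pytest.fixture(scope="session")
def dataset():
    return generate(STUDY_SPEC)


@pytest.fixture(scope="session")
def pipeline_result(dataset, tmp_path_factory):
    """Full pipeline run over the synthetic corpus (computed once)."""
    base = tmp_path_factory.mktemp("e2e")
    paths = dataset.write(base / "data")
    gene_table = GeneSymbolTable.from_tsv(str(paths["gene_table"]))
    return run_pipeline(
        RunConfig(),
        [(tag, paths[tag]) for tag in dataset.ground_truth.tags],
        base / "out",
        gene_table=gene_table,
        human_genes=dataset.human_genes,
    )
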