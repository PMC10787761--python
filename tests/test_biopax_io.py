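"""Parser and xref-table behaviour against hand-written and generated OWL."""

from __future__ import annotations

import random

import pytest
from lxml import etree

from ginkit.biopax_io import (
    build_xref_table,
    dangling_references,
    entities_to_frame,
    normalize_source_db,
    parse_biopax,
)
from ginkit.diagnostics import Diagnostics

EMPTY_OWL = """<?xml version="1.0"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:bp="http://www.biopax.org/release/biopax-level3.owl#"/>
"""


def test_parse_counts_classes(tiny_owl):
    entities = parse_biopax(tiny_owl)
    by_class: dict[str, int] = {}
    for entity in entities:
        by_class[entity.biopax_class] = by_class.get(entity.biopax_class, 0) + 1
    assert by_class["BiochemicalReaction"] == 1
    assert by_class["SmallMolecule"] == 2
    assert by_class["Protein"] == 2
    assert by_class["Catalysis"] == 1
    assert by_class["Complex"] == 1


def test_parse_empty_document():
    assert parse_biopax(EMPTY_OWL) == []


def test_complex_components_match_xpath_scan(tiny_owl):
    """Component list equals a brute-force XPath scan of the raw XML."""
    entities = {e.entity_id: e for e in parse_biopax(tiny_owl)}
    root = etree.fromstring(tiny_owl.encode())
    expected = [
        ref.get("{http://www.w3.org/1999/02/22-rdf-syntax-ns#}resource").lstrip("#")
        for ref in root.xpath(
            "//bp:Complex[@rdf:ID='cplx1']/bp:component",
            namespaces={
                "bp": "http://www.biopax.org/release/biopax-level3.owl#",
                "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
            },
        )
    ]
    assert entities["cplx1"].prop("component") == expected == ["prot_enz", "prot_b"]


def test_malformed_xml_names_line():
    bad = "<?xml version='1.0'?>\n<rdf:RDF xmlns:rdf='http://www.w3.org/1999/02/22-rdf-syntax-ns#'>\n<unclosed>\n</rdf:RDF>"
    with pytest.raises(etree.XMLSyntaxError, match=r"line \d+"):
        parse_biopax(bad)


def test_property_order_and_literals_preserved(tiny_owl):
    entities = {e.entity_id: e for e in parse_biopax(tiny_owl)}
    assert entities["rxn1"].prop("left") == ["sm_atp", "sm_glc"]
    assert entities["sm_atp"].display_name == "ATP"
    assert entities["xref_chebi"].first("id") == "15422"


def test_no_quadruple_lost_on_serialisation(tiny_owl):
    """Every (entity, class, property, value) written in the document shows
    up in the flat table."""
    frame = entities_to_frame(parse_biopax(tiny_owl))
    quads = set(
        frame[["entity_id", "biopax_class", "property", "value"]].itertuples(index=False)
    )
    assert ("rxn1", "BiochemicalReaction", "left", "sm_glc") in {tuple(q) for q in quads}
    assert ("cat1", "Catalysis", "controlled", "rxn1") in {tuple(q) for q in quads}
    assert ("sm_atp", "SmallMolecule", "xref", "xref_cid") in {tuple(q) for q in quads}


def test_dangling_reference_detection(tiny_owl):
    broken = tiny_owl.replace('rdf:resource="#prot_b"', 'rdf:resource="#ghost"')
    assert dangling_references(parse_biopax(broken)) == {"ghost"}
    assert dangling_references(parse_biopax(tiny_owl)) == set()


def test_source_db_normalisation():
    assert normalize_source_db("PubChem-Compound") == "CID"
    assert normalize_source_db("uniprot knowledgebase") == "UniProt"
    assert normalize_source_db("ChEBI") == "ChEBI"
    assert normalize_source_db("SomeOther DB") == "someother db"


def test_xref_table_tiny_document(tiny_owl):
    entities = parse_biopax(tiny_owl)
    table = build_xref_table(entities)
    assert ("prot_enz", "UniProt", "P_FIX1") in table  # inherited via entityReference
    atp = [x for x in table if x.entity_id == "sm_atp"]
    assert {(x.source_db, x.external_id) for x in atp} == {
        ("ChEBI", "15422"), ("CID", "5957"),
    }


def test_xref_table_order_independent_and_counts(dataset):
    """Entry count equals a brute-force scan of the raw XML; permuting
    entity order changes nothing."""
    doc = dataset.documents["db1"]
    entities = parse_biopax(doc)
    table = build_xref_table(entities)

    root = etree.fromstring(doc.encode())
    ns = {
        "bp": "http://www.biopax.org/release/biopax-level3.owl#",
        "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    }
    # brute force: count distinct (physical entity, db, id) via the XML only
    xref_fields = {}
    for xref_class in ("UnificationXref", "RelationshipXref"):
        for element in root.xpath(f"//bp:{xref_class}", namespaces=ns):
            xid = element.get("{http://www.w3.org/1999/02/22-rdf-syntax-ns#}ID")
            db = element.xpath("string(bp:db)", namespaces=ns)
            ext = element.xpath("string(bp:id)", namespaces=ns)
            xref_fields[xid] = (db, ext)
    owners = set()
    for cls in ("Protein", "SmallMolecule", "Complex"):
        for element in root.xpath(f"//bp:{cls}", namespaces=ns):
            eid = element.get("{http://www.w3.org/1999/02/22-rdf-syntax-ns#}ID")
            linked = [
                r.get("{http://www.w3.org/1999/02/22-rdf-syntax-ns#}resource").lstrip("#")
                for r in element.xpath("bp:xref", namespaces=ns)
            ]
            for ref in element.xpath("bp:entityReference", namespaces=ns):
                rid = ref.get("{http://www.w3.org/1999/02/22-rdf-syntax-ns#}resource").lstrip("#")
                for holder in root.xpath(f"//*[@rdf:ID='{rid}']", namespaces=ns):
                    linked.extend(
                        r.get("{http://www.w3.org/1999/02/22-rdf-syntax-ns#}resource").lstrip("#")
                        for r in holder.xpath("bp:xref", namespaces=ns)
                    )
            for xid in linked:
                if xid in xref_fields:
                    owners.add((eid, *xref_fields[xid]))
    expected = {(eid, normalize_source_db(db), ext) for eid, db, ext in owners}
    assert {(x.entity_id, x.source_db, x.external_id) for x in table} == expected

    shuffled = list(entities)
    random.Random(0).shuffle(shuffled)
    assert build_xref_table(shuffled) == table


def test_xref_missing_fields_counted():
    doc = """<?xml version="1.0"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:bp="http://www.biopax.org/release/biopax-level3.owl#">
  <bp:UnificationXref rdf:ID="bad1">
    <bp:db rdf:datatype="http://www.w3.org/2001/XMLSchema#string">ChEBI</bp:db>
  </bp:UnificationXref>
  <bp:SmallMolecule rdf:ID="sm1">
    <bp:xref rdf:resource="#bad1"/>
  </bp:SmallMolecule>
</rdf:RDF>"""
    diag = Diagnostics()
    table = build_xref_table(parse_biopax(doc), diag=diag)
    assert table == []
    assert diag["xref_missing_db_or_id"] == 1
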