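"""Streaming adapters: field mapping, compression, error policy, memory bounds."""

import gzip
import io
import json

import pytest

from xrefdb.ingest import (
    ColumnSpec,
    FormatError,
    StreamStats,
    XrefRule,
    ingest_gff3,
    ingest_json,
    ingest_tsv,
    ingest_xml,
)

CHEBI_SPEC = ColumnSpec(
    identifier=0,
    attributes={"name": 1},
    xrefs=[XrefRule(source=2, target="kegg")],
)


def _tsv(text: str) -> io.BytesIO:
    return io.BytesIO(text.encode())


class TestTsv:
    def test_direct_field_mapping(self):
        recs = list(ingest_tsv(_tsv("CHEBI:15377\twater\tC00001\n"), CHEBI_SPEC))
        assert len(recs) == 1
        rec = recs[0]
        assert rec.identifier == "CHEBI:15377"
        assert rec.attributes == {"name": "water"}
        assert [(x.target_dataset, x.target_id) for x in rec.xrefs] == [("kegg", "C00001")]

    def test_empty_stream(self):
        stats = StreamStats()
        assert list(ingest_tsv(_tsv(""), CHEBI_SPEC, stats)) == []
        assert stats.records_emitted == 0

    def test_header_and_count_conservation(self):
        lines = ["id\tname\tkegg"] + [f"CHEBI:{i}\tname{i}\tC{i}" for i in range(500)]
        lines.insert(100, "\tmissing-id\tC")  # malformed: empty identifier
        spec = ColumnSpec(identifier=0, attributes={"name": 1}, header=True,
                          xrefs=[XrefRule(source=2, target="kegg")],
                          max_error_fraction=0.05)
        stats = StreamStats()
        recs = list(ingest_tsv(_tsv("\n".join(lines) + "\n"), spec, stats))
        assert len(recs) == 500
        assert stats.records_emitted + stats.records_skipped == 501

    def test_error_threshold(self):
        bad = "x\n" * 10 + "CHEBI:1\tok\tC1\n"
        with pytest.raises(FormatError):
            list(ingest_tsv(_tsv(bad), CHEBI_SPEC))

    def test_gzip_twin_identical(self):
        raw = "\n".join(f"CHEBI:{i}\tname{i}\tC{i}" for i in range(50)).encode()
        plain = list(ingest_tsv(io.BytesIO(raw), CHEBI_SPEC))
        zipped = list(ingest_tsv(io.BytesIO(gzip.compress(raw)), CHEBI_SPEC))
        assert plain == zipped


HGNC_SPEC = ColumnSpec(
    identifier="hgnc_id",
    attributes={"symbol": "symbol"},
    keywords=["symbol"],
    xrefs=[XrefRule(source="ensembl_gene_id", target="ensembl")],
)


class TestJson:
    def test_gene_symbol_becomes_keyword(self):
        doc = [{"symbol": "CASP8", "hgnc_id": "HGNC:1509", "ensembl_gene_id": "ENSG00000064012"}]
        recs = list(ingest_json(io.BytesIO(json.dumps(doc).encode()), HGNC_SPEC))
        assert recs[0].identifier == "HGNC:1509"
        assert recs[0].keywords == ["CASP8"]
        assert recs[0].xrefs[0].target_id == "ENSG00000064012"

    def test_missing_identifier_skipped_and_counted(self):
        doc = [{"symbol": "A"}, {"hgnc_id": "HGNC:2", "symbol": "B"}]
        spec = ColumnSpec(identifier="hgnc_id", keywords=["symbol"], max_error_fraction=0.6)
        stats = StreamStats()
        recs = list(ingest_json(io.BytesIO(json.dumps(doc).encode()), spec, stats))
        assert [r.identifier for r in recs] == ["HGNC:2"]
        assert stats.records_skipped == 1

    def test_json_lines(self):
        body = b'{"hgnc_id": "HGNC:1", "symbol": "A"}\n{"hgnc_id": "HGNC:2", "symbol": "B"}\n'
        recs = list(ingest_json(io.BytesIO(body), HGNC_SPEC))
        assert [r.identifier for r in recs] == ["HGNC:1", "HGNC:2"]

    def test_invalid_json_raises_format_error(self):
        with pytest.raises(FormatError):
            list(ingest_json(io.BytesIO(b"[{bad json}]"), HGNC_SPEC))

    def test_nested_dotted_path(self):
        doc = [{"id": "X1", "loc": {"chr": "7"}}]
        spec = ColumnSpec(identifier="id", attributes={"chrom": "loc.chr"})
        recs = list(ingest_json(io.BytesIO(json.dumps(doc).encode()), spec))
        assert recs[0].attributes == {"chrom": "7"}


UNIPROT_XML = """<?xml version="1.0"?>
<uniprot>
  <entry reviewed="true">
    <accession>O43657</accession>
    <protein><fullName>Tetraspanin-6</fullName><fullName>TSN6</fullName></protein>
    <organism taxid="9606"/>
    <dbReference type="Ensembl" id="ENSG000001"/>
    <dbReference type="GO" id="GO:0005515"/>
    <dbReference type="GO" id="GO:0005515"/>
    <dbReference type="PDB" id="1ABC"/>
  </entry>
</uniprot>
"""

UNIPROT_SPEC = ColumnSpec(
    record_tag="entry",
    identifier="accession",
    attributes={"reviewed": "@reviewed", "names": "protein/*[]"},
    attr_types={"reviewed": "bool"},
    xrefs=[
        XrefRule(source="dbReference", type_attr="type",
                 targets={"Ensembl": "ensembl", "GO": "go"}),
        XrefRule(source="organism", id_attr="taxid", target="taxonomy"),
    ],
)


class TestXml:
    def test_protein_entry(self):
        recs = list(ingest_xml(io.BytesIO(UNIPROT_XML.encode()), UNIPROT_SPEC))
        assert len(recs) == 1
        rec = recs[0]
        assert rec.identifier == "O43657"
        assert rec.attributes["reviewed"] is True
        assert rec.attributes["names"] == ["Tetraspanin-6", "TSN6"]
        targets = [(x.target_dataset, x.target_id) for x in rec.xrefs]
        # duplicate dbReference emitted twice here; deduplicated at merge time
        assert targets.count(("go", "GO:0005515")) == 2
        assert ("taxonomy", "9606") in targets
        assert all(t[0] != "PDB" for t in targets)  # unmapped types ignored

    def test_parent_relation_stub(self):
        xml = b'<t><taxon id="595" parent="59201" name="strain A"/></t>'
        spec = ColumnSpec(
            record_tag="taxon", identifier="@id",
            attributes={"name": "@name"}, keywords=["@name"],
            parent_relation=("@parent", "taxchild"),
        )
        recs = list(ingest_xml(io.BytesIO(xml), spec))
        assert [r.identifier for r in recs] == ["595", "59201"]
        stub = recs[1]
        assert stub.stub is True
        assert [(x.target_dataset, x.target_id) for x in stub.xrefs] == [("taxchild", "595")]

    def test_malformed_xml(self):
        with pytest.raises(FormatError):
            list(ingest_xml(io.BytesIO(b"<a><entry>unclosed"), UNIPROT_SPEC))


GFF3 = """##gff-version 3
##species http://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=9606
X\tsrc\tgene\t100500000\t100501000\t.\t+\t.\tID=gene:ENSGTEST1;description=test SopD protein;Ontology_term=GO:1,GO:2
X\tsrc\tmRNA\t100500000\t100501000\t.\t+\t.\tID=transcript:ENSTTEST1;Parent=gene:ENSGTEST1
X\tsrc\texon\t100500000\t100500100\t.\t+\t.\tID=exon1
X\tsrc\tgene\tnotanumber\t5\t.\t+\t.\tID=gene:BAD
"""


class TestGff3:
    def test_gene_and_transcript(self):
        stats = StreamStats()
        recs = list(ingest_gff3(io.BytesIO(GFF3.encode()), stats=stats, max_error_fraction=0.5))
        gene = recs[0]
        assert gene.dataset == "ensembl"
        assert gene.attributes["seq_region"] == "X"
        assert gene.attributes["start"] == 100500000
        assert gene.attributes["end"] == 100501000
        assert gene.attributes["strand"] == "+"
        assert "SopD" in gene.attributes["description"]
        targets = {(x.target_dataset, x.target_id) for x in gene.xrefs}
        assert ("taxonomy", "9606") in targets and ("go", "GO:1") in targets
        # transcript + the gene-side stub
        tr = recs[1]
        assert tr.dataset == "transcript" and tr.identifier == "ENSTTEST1"
        assert ("ensembl", "ENSGTEST1") in {(x.target_dataset, x.target_id) for x in tr.xrefs}
        stub = recs[2]
        assert stub.stub and stub.identifier == "ENSGTEST1"
        assert [(x.target_dataset, x.target_id) for x in stub.xrefs] == [("transcript", "ENSTTEST1")]
        # non-numeric coordinates skipped and counted; exon line ignored silently
        assert stats.records_skipped == 1
        assert stats.records_emitted == 2

    def test_gzip_twin_identical(self):
        plain = list(ingest_gff3(io.BytesIO(GFF3.encode()), max_error_fraction=0.5))
        zipped = list(ingest_gff3(io.BytesIO(gzip.compress(GFF3.encode())), max_error_fraction=0.5))
        assert plain == zipped
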