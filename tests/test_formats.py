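"""FASTA input, the output format family, and XML canonicality."""

import random

import pytest

from sigscan.formats import (FormatError, NucleotideRecord, OrfRef,
                             ProteinResult, ProteinXref, ResultDocument,
                             convert, make_document, read_fasta, read_xml,
                             write_gff3, write_json, write_tsv, write_xml)
from sigscan.integration import AnnotatedMatch
from sigscan.model import (FILTERED_IN, Entry, GoTerm, Location, Match,
                           PathwayXref, canonicalize_and_checksum)

AA = "ACDEFGHIKLMNPQRSTVWY"


def am(md5, acc="SIG1", analysis="LIB", locs=((2, 5, None),), entry=None):
    locations = tuple(Location(s, e, sc) for s, e, sc in locs)
    m = Match(protein_md5=md5, signature_accession=acc,
              locations=locations, status=FILTERED_IN)
    return AnnotatedMatch(
        match=m, analysis=analysis, signature_name=f"{acc} name",
        entry=entry,
        go_terms=entry.go_terms if entry else frozenset(),
        pathways=entry.pathway_xrefs if entry else frozenset())


def simple_doc(with_entry=True, nucleotide=False):
    prot = canonicalize_and_checksum("p1", "MKVWAQPLS")
    entry = None
    if with_entry:
        entry = Entry("E1", "entry one", "family",
                      signature_accessions=frozenset({"SIG1"}),
                      go_terms=frozenset({GoTerm("GO:0001", "MF", "t")}),
                      pathway_xrefs=frozenset(
                          {PathwayXref("KEGG", "K1", "n")}))
    orf = OrfRef("contig1", "+", 10, 39) if nucleotide else None
    p = ProteinResult(
        md5=prot.md5, length=prot.length, residues=prot.residues,
        xrefs=(ProteinXref("p1", orf),),
        matches=(am(prot.md5, entry=entry),))
    nts = ((NucleotideRecord("contig1", "A" * 60, 60),) if nucleotide
           else ())
    return make_document(date="2020-01-01", analyses=[("LIB", "1.0")],
                         proteins=[p], nucleotides=nts)


class TestReadFasta:
    def test_two_records_with_wrapping(self, tmp_path):
        path = tmp_path / "in.fasta"
        path.write_text(">a desc here\nMKV\nWAQ\n\n>b\nPEPTIDE\n")
        seqs = read_fasta(str(path))
        assert [(s.id, s.length) for s in seqs] == [("a", 6), ("b", 7)]
        assert seqs[0].residues == "MKVWAQ"

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">a\nMKV\n>a\nWAQ\n")
        with pytest.raises(FormatError):
            read_fasta(str(path))


class TestTsv:
    def rows(self, doc, tmp_path):
        path = tmp_path / "out.tsv"
        write_tsv(doc, str(path))
        return [l.split("\t") for l in
                path.read_text().rstrip("\n").split("\n") if l]

    def test_fifteen_columns_with_annotation(self, tmp_path):
        rows = self.rows(simple_doc(), tmp_path)
        assert len(rows) == 1
        row = rows[0]
        assert len(row) == 15
        assert row[0] == "p1" and row[3] == "LIB" and row[4] == "SIG1"
        assert row[6] == "2" and row[7] == "5"
        assert row[11] == "E1" and row[13] == "GO:0001"
        assert row[14] == "KEGG:K1"

    def test_unintegrated_signature_gets_dashes(self, tmp_path):
        rows = self.rows(simple_doc(with_entry=False), tmp_path)
        assert rows[0][11] == "-" and rows[0][12] == "-"
        assert rows[0][13] == "-" and rows[0][14] == "-"

    def test_multi_location_match_gives_one_row_per_location(self,
                                                             tmp_path):
        prot = canonicalize_and_checksum("p1", "MKVWAQPLS")
        p = ProteinResult(
            md5=prot.md5, length=prot.length, residues=prot.residues,
            xrefs=(ProteinXref("p1"),),
            matches=(am(prot.md5, locs=((1, 3, 7.5), (5, 8, 2.25))),))
        doc = make_document("2020-01-01", [("LIB", "1.0")], [p])
        rows = self.rows(doc, tmp_path)
        assert len(rows) == 2
        assert rows[0][:6] == rows[1][:6]
        assert (rows[0][6], rows[0][7], rows[0][8]) == ("1", "3", "7.500")


class TestXmlRoundTrip:
    def test_round_trip_equality(self, tmp_path):
        doc = simple_doc(nucleotide=True)
        path = tmp_path / "out.xml"
        write_xml(doc, str(path))
        assert read_xml(str(path)) == doc

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.xml"
        path.write_text("")
        with pytest.raises(FormatError):
            read_xml(str(path))

    def test_schema_violation_names_element_and_line(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<protein-matches tool-version='0' date='d'>"
                        "\n<proteins>\n<protein length='3'>"
                        "<sequence>MKV</sequence></protein>"
                        "</proteins></protein-matches>")
        with pytest.raises(FormatError) as exc:
            read_xml(str(path))
        assert "md5" in str(exc.value) and "line" in str(exc.value)


class TestGff3:
    def test_protein_match_coordinates(self, tmp_path):
        path = tmp_path / "out.gff3"
        write_gff3(simple_doc(), str(path))
        lines = path.read_text().split("\n")
        assert lines[0] == "##gff-version 3"
        feature = [l for l in lines if "\tprotein_match\t" in l][0]
        cols = feature.split("\t")
        assert cols[0] == "p1" and (cols[3], cols[4]) == ("2", "5")
        assert cols[6] == "."
        assert "##FASTA" in lines

    def test_nucleotide_projection_through_orf(self, tmp_path):
        path = tmp_path / "nt.gff3"
        write_gff3(simple_doc(nucleotide=True), str(path))
        lines = path.read_text().split("\n")
        proj = [l for l in lines if l.startswith("contig1\t")
                and "\tprotein_match\t" in l]
        assert len(proj) == 1
        cols = proj[0].split("\t")
        # ORF at nt 10..39, residues 2..5: start 10+3(2-1)=13, end 10+3*5-1=24
        assert (cols[3], cols[4], cols[6]) == ("13", "24", "+")
        orf_lines = [l for l in lines if "\tORF\t" in l]
        assert len(orf_lines) == 1

    def test_zero_match_document_is_header_and_fasta_only(self, tmp_path):
        prot = canonicalize_and_checksum("p1", "MKV")
        p = ProteinResult(md5=prot.md5, length=3, residues="MKV",
                          xrefs=(ProteinXref("p1"),), matches=())
        doc = make_document("2020-01-01", [("LIB", "1.0")], [p])
        path = tmp_path / "empty.gff3"
        write_gff3(doc, str(path))
        body = path.read_text()
        assert "protein_match" not in body
        assert body.startswith("##gff-version 3")
        assert ">p1" in body


def random_document(rng):
    analyses = [("LIB", "1.0")]
    proteins = []
    for i in range(rng.randint(1, 4)):
        residues = "".join(rng.choice(AA) for _ in range(rng.randint(9, 30)))
        prot = canonicalize_and_checksum(f"p{i}", residues)
        entry = None
        if rng.random() < 0.6:
            entry = Entry(f"E{i}", f"entry {i}", "domain",
                          signature_accessions=frozenset({f"S{i}"}),
                          go_terms=frozenset({GoTerm(f"GO:{i:07d}", "BP",
                                                     "term")}),
                          pathway_xrefs=frozenset(
                              {PathwayXref("KEGG", f"K{i}", "p")}))
        matches = []
        for j in range(rng.randint(0, 3)):
            s = rng.randint(1, prot.length - 1)
            e = rng.randint(s, prot.length)
            score = round(rng.uniform(0, 50), 3) if rng.random() < 0.5 \
                else None
            matches.append(am(prot.md5, acc=f"S{j}",
                              locs=((s, e, score),), entry=entry))
        use_orf = rng.random() < 0.3
        orf = OrfRef("contig1", rng.choice("+-"),
                     10, 9 + 3 * prot.length) if use_orf else None
        proteins.append(ProteinResult(
            md5=prot.md5, length=prot.length, residues=prot.residues,
            xrefs=(ProteinXref(f"p{i}", orf),), matches=tuple(matches)))
    nts = ((NucleotideRecord("contig1", "ACGT" * 30, 120),)
           if any(x.orf for p in proteins for x in p.xrefs) else ())
    return make_document("2020-01-01", analyses, proteins, nts)


class TestConvertConsistency:
    @pytest.mark.parametrize("target, writer", [
        ("tsv", write_tsv), ("gff3", write_gff3), ("json", write_json)])
    def test_convert_byte_equals_direct_writer(self, tmp_path, target,
                                               writer):
        rng = random.Random(4)
        for k in range(8):
            doc = random_document(rng)
            xml = tmp_path / f"{target}{k}.xml"
            write_xml(doc, str(xml))
            direct = tmp_path / f"{target}{k}.direct"
            writer(doc, str(direct))
            converted = tmp_path / f"{target}{k}.converted"
            convert(str(xml), target, str(converted))
            assert converted.read_bytes() == direct.read_bytes()

    def test_round_trip_identity_on_random_documents(self, tmp_path):
        rng = random.Random(11)
        for k in range(20):
            doc = random_document(rng)
            path = tmp_path / f"r{k}.xml"
            write_xml(doc, str(path))
            assert read_xml(str(path)) == doc

    def test_unsupported_targets_rejected(self, tmp_path):
        doc = simple_doc()
        xml = tmp_path / "d.xml"
        write_xml(doc, str(xml))
        for target in ("html", "svg", "raw", "nonsense"):
            with pytest.raises(ValueError):
                convert(str(xml), target, str(tmp_path / "x"))

    def test_repeated_writes_are_byte_identical(self, tmp_path):
        doc = simple_doc(nucleotide=True)
        a, b = tmp_path / "a.xml", tmp_path / "b.xml"
        write_xml(doc, str(a))
        write_xml(doc, str(b))
        assert a.read_bytes() == b.read_bytes()
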