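"""Result document and the output format family.

The in-memory :class:`ResultDocument` is the single source for every
writer.  Its XML serialization is canonical and lossless
(``read_xml(write_xml(doc)) == doc``); TSV, GFF3 and JSON are
projections of the same document, so converting a stored XML file with
:func:`convert` is byte-identical to writing the target format
directly.

All coordinates are 1-based inclusive.  Output is deterministic: rows
and elements are sorted canonically and the run date is an explicit
document field (injectable, so byte-equality is testable).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

from Bio import SeqIO
from lxml import etree

from .integration import AnnotatedMatch
from .model import (FILTERED_IN, Entry, GoTerm, Location, Match,
                    NucleotideSequence, PathwayXref, ProteinSequence,
                    SequenceError, canonicalize_and_checksum,
                    canonicalize_nucleotide)
from .orfs import OpenReadingFrame, map_to_nucleotide

TOOL_VERSION = "0.1.0"
TSV_COLUMNS = 15


class FormatError(ValueError):
    """Malformed input document (parse or schema violation)."""


@dataclass(frozen=True)
class OrfRef:
    """Provenance of an ORF-derived protein: where on which parent
    nucleotide sequence, and on which strand, it was translated from."""

    parent_id: str
    strand: str
    nt_start: int
    nt_end: int


@dataclass(frozen=True)
class ProteinXref:
    """One user-supplied identifier carrying this protein, with ORF
    provenance for nucleotide runs."""

    id: str
    orf: Optional[OrfRef] = None


@dataclass(frozen=True)
class ProteinResult:
    md5: str
    length: int
    residues: str
    xrefs: Tuple[ProteinXref, ...]
    matches: Tuple[AnnotatedMatch, ...]


@dataclass(frozen=True)
class NucleotideRecord:
    id: str
    residues: str
    length: int


@dataclass(frozen=True)
class ResultDocument:
    tool_version: str
    date: str
    analyses: Tuple[Tuple[str, str], ...]  # (name, version), sorted
    proteins: Tuple[ProteinResult, ...]
    nucleotides: Tuple[NucleotideRecord, ...] = ()


def _match_key(am: AnnotatedMatch):
    loc = am.match.locations[0]
    return (am.analysis, am.match.signature_accession, loc.start, loc.stop)


def make_document(date: str, analyses: Sequence[Tuple[str, str]],
                  proteins: Sequence[ProteinResult],
                  nucleotides: Sequence[NucleotideRecord] = ()
                  ) -> ResultDocument:
    """Assemble a canonical document: analyses, proteins, xrefs and
    matches all sorted; only filtered-in matches are admitted."""
    prots = []
    for p in proteins:
        for am in p.matches:
            if am.match.status != FILTERED_IN:
                raise ValueError("documents carry filtered_in matches only")
        prots.append(ProteinResult(
            md5=p.md5, length=p.length, residues=p.residues,
            xrefs=tuple(sorted(p.xrefs, key=lambda x: x.id)),
            matches=tuple(sorted(p.matches, key=_match_key))))
    prots.sort(key=lambda p: p.md5)
    return ResultDocument(
        tool_version=TOOL_VERSION, date=date,
        analyses=tuple(sorted(analyses)),
        proteins=tuple(prots),
        nucleotides=tuple(sorted(nucleotides, key=lambda n: n.id)))


# ---------------------------------------------------------------------------
# FASTA input

def read_fasta(path: str, kind: str = "protein"
               ) -> List[Union[ProteinSequence, NucleotideSequence]]:
    """Read a FASTA file into validated sequences.

    Identifiers are the header token before the first whitespace;
    duplicate identifiers are rejected; line wrapping and blank lines
    are tolerated.  Alphabet validation is delegated to the core model
    and raises :class:`SequenceError`.
    """
    if kind not in ("protein", "nucleotide"):
        raise ValueError(f"unknown sequence kind {kind!r}")
    seen = set()
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq)
        if kind == "protein":
            out.append(canonicalize_and_checksum(rec.id, raw))
        else:
            out.append(canonicalize_nucleotide(rec.id, raw))
    return out


def write_fasta(records: Sequence[Tuple[str, str]], path: str,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, residues in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(residues), width):
                fh.write(residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# TSV

def _fmt_score(score: Optional[float]) -> str:
    return "-" if score is None else f"{score:.3f}"


def _go_field(am: AnnotatedMatch) -> str:
    if not am.go_terms:
        return "-"
    return "|".join(g.go_id for g in sorted(am.go_terms))


def _pathway_field(am: AnnotatedMatch) -> str:
    if not am.pathways:
        return "-"
    return "|".join(p.key for p in sorted(am.pathways))


def _tsv_rows(doc: ResultDocument):
    rows = []
    for p in doc.proteins:
        for xref in p.xrefs:
            for am in p.matches:
                entry_acc = am.entry.accession if am.entry else "-"
                entry_name = am.entry.name if am.entry else "-"
                for loc in am.match.locations:
                    rows.append((
                        xref.id, p.md5, str(p.length), am.analysis,
                        am.match.signature_accession,
                        am.signature_name or "-",
                        str(loc.start), str(loc.stop),
                        _fmt_score(loc.score), am.match.status, doc.date,
                        entry_acc, entry_name,
                        _go_field(am), _pathway_field(am)))
    rows.sort(key=lambda r: (r[0], r[3], r[4], int(r[6]), int(r[7])))
    return rows


def write_tsv(doc: ResultDocument, path: str) -> None:
    """One row per (identifier, match location); 15 tab-separated
    columns; missing values as '-'; sorted by (id, analysis, signature
    accession, start)."""
    with open(path, "w") as fh:
        for row in _tsv_rows(doc):
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# XML (canonical, lossless)

def _entry_to_xml(parent, entry: Entry):
    el = etree.SubElement(parent, "entry",
                          accession=entry.accession, name=entry.name,
                          type=entry.type)
    if entry.signature_accessions:
        el.set("signatures", " ".join(sorted(entry.signature_accessions)))
    for g in sorted(entry.go_terms):
        etree.SubElement(el, "go", id=g.go_id, category=g.category,
                         term=g.term)
    for p in sorted(entry.pathway_xrefs):
        etree.SubElement(el, "pathway", database=p.database,
                         id=p.pathway_id, name=p.name)
    return el


def _entry_from_xml(el) -> Entry:
    return Entry(
        accession=_req(el, "accession"), name=_req(el, "name"),
        type=_req(el, "type"),
        signature_accessions=frozenset(el.get("signatures", "").split()),
        go_terms=frozenset(
            GoTerm(go_id=_req(g, "id"), category=g.get("category", ""),
                   term=g.get("term", ""))
            for g in el.findall("go")),
        pathway_xrefs=frozenset(
            PathwayXref(database=_req(p, "database"), pathway_id=_req(p, "id"),
                        name=p.get("name", ""))
            for p in el.findall("pathway")))


def write_xml(doc: ResultDocument, path: str) -> None:
    root = etree.Element("protein-matches",
                         {"tool-version": doc.tool_version,
                          "date": doc.date})
    analyses = etree.SubElement(root, "analyses")
    for name, version in doc.analyses:
        etree.SubElement(analyses, "analysis", name=name, version=version)
    if doc.nucleotides:
        nts = etree.SubElement(root, "nucleotide-sequences")
        for n in doc.nucleotides:
            nel = etree.SubElement(nts, "nucleotide", id=n.id,
                                   length=str(n.length))
            seq = etree.SubElement(nel, "sequence")
            seq.text = n.residues
    prots = etree.SubElement(root, "proteins")
    for p in doc.proteins:
        pel = etree.SubElement(prots, "protein", md5=p.md5,
                               length=str(p.length))
        seq = etree.SubElement(pel, "sequence")
        seq.text = p.residues
        for x in p.xrefs:
            attrs = {"id": x.id}
            if x.orf is not None:
                attrs.update({"parent": x.orf.parent_id,
                              "strand": x.orf.strand,
                              "nt-start": str(x.orf.nt_start),
                              "nt-end": str(x.orf.nt_end)})
            etree.SubElement(pel, "xref", attrs)
        for am in p.matches:
            mel = etree.SubElement(pel, "match",
                                   analysis=am.analysis,
                                   signature=am.match.signature_accession,
                                   status=am.match.status)
            mel.set("signature-name", am.signature_name)
            if am.entry is not None:
                _entry_to_xml(mel, am.entry)
            locs = etree.SubElement(mel, "locations")
            for loc in am.match.locations:
                attrs = {"start": str(loc.start), "stop": str(loc.stop)}
                if loc.score is not None:
                    attrs["score"] = repr(loc.score)
                if loc.evalue is not None:
                    attrs["evalue"] = repr(loc.evalue)
                etree.SubElement(locs, "location", attrs)
    tree = etree.ElementTree(root)
    etree.indent(tree, space="  ")
    tree.write(path, xml_declaration=True, encoding="UTF-8")
    with open(path, "ab") as fh:
        fh.write(b"\n")


def _req(el, attr: str) -> str:
    val = el.get(attr)
    if val is None:
        raise FormatError(
            f"element <{el.tag}> at line {el.sourceline}: "
            f"missing required attribute {attr!r}")
    return val


def read_xml(path: str) -> ResultDocument:
    """Parse a result XML file back into an equal
    :class:`ResultDocument`; parse and schema errors carry the element
    and line number."""
    if os.path.getsize(path) == 0:
        raise FormatError(f"{path}: empty file")
    try:
        tree = etree.parse(path)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: {exc}") from None
    root = tree.getroot()
    if root.tag != "protein-matches":
        raise FormatError(
            f"{path}: unexpected root element <{root.tag}> "
            f"at line {root.sourceline}")
    analyses = tuple((_req(a, "name"), _req(a, "version"))
                     for a in root.findall("analyses/analysis"))
    nucleotides = []
    for nel in root.findall("nucleotide-sequences/nucleotide"):
        seq = nel.findtext("sequence") or ""
        nucleotides.append(NucleotideRecord(
            id=_req(nel, "id"), residues=seq, length=int(_req(nel, "length"))))
    proteins = []
    for pel in root.findall("proteins/protein"):
        md5 = _req(pel, "md5")
        residues = pel.findtext("sequence") or ""
        xrefs = []
        for x in pel.findall("xref"):
            orf = None
            if x.get("parent") is not None:
                orf = OrfRef(parent_id=_req(x, "parent"),
                             strand=_req(x, "strand"),
                             nt_start=int(_req(x, "nt-start")),
                             nt_end=int(_req(x, "nt-end")))
            xrefs.append(ProteinXref(id=_req(x, "id"), orf=orf))
        matches = []
        for mel in pel.findall("match"):
            entry_el = mel.find("entry")
            entry = _entry_from_xml(entry_el) if entry_el is not None else None
            locations = tuple(
                Location(start=int(_req(l, "start")),
                         stop=int(_req(l, "stop")),
                         score=(float(l.get("score"))
                                if l.get("score") is not None else None),
                         evalue=(float(l.get("evalue"))
                                 if l.get("evalue") is not None else None))
                for l in mel.findall("locations/location"))
            if not locations:
                raise FormatError(
                    f"element <match> at line {mel.sourceline}: no locations")
            m = Match(protein_md5=md5,
                      signature_accession=_req(mel, "signature"),
                      locations=locations, status=_req(mel, "status"))
            matches.append(AnnotatedMatch(
                match=m, analysis=_req(mel, "analysis"),
                signature_name=mel.get("signature-name", "-"),
                entry=entry,
                go_terms=entry.go_terms if entry else frozenset(),
                pathways=entry.pathway_xrefs if entry else frozenset()))
        proteins.append(ProteinResult(
            md5=md5, length=int(_req(pel, "length")), residues=residues,
            xrefs=tuple(xrefs), matches=tuple(matches)))
    return ResultDocument(tool_version=_req(root, "tool-version"),
                          date=_req(root, "date"),
                          analyses=analyses, proteins=tuple(proteins),
                          nucleotides=tuple(nucleotides))


# ---------------------------------------------------------------------------
# GFF3

def _orf_for(p: ProteinResult, ref: OrfRef) -> OpenReadingFrame:
    prot = ProteinSequence(id=p.md5, residues=p.residues, md5=p.md5,
                           length=p.length)
    return OpenReadingFrame(parent_id=ref.parent_id, strand=ref.strand,
                            nt_start=ref.nt_start, nt_end=ref.nt_end,
                            protein=prot)


def _gff_escape(s: str) -> str:
    return (s.replace("%", "%25").replace(";", "%3B").replace("=", "%3D")
            .replace(",", "%2C"))


def write_gff3(doc: ResultDocument, path: str) -> None:
    """GFF3 projection: one ``protein_match`` feature per match
    location on each protein identifier; for nucleotide runs
    additionally one ``ORF`` feature per translated ORF and one
    projected match feature per location on the parent nucleotide
    sequence (coordinates via the ORF coordinate mapping, strand from
    the ORF).  The analyzed protein sequences are appended after
    ``##FASTA``."""
    lines = ["##gff-version 3"]
    # ORF features first so projected match lines have a visible parent
    orf_lines = []
    proj_lines = []
    prot_lines = []
    fasta: list[tuple[str, str]] = []
    counters: dict[str, int] = {}

    def next_id(seqid: str) -> str:
        counters[seqid] = counters.get(seqid, 0) + 1
        return f"{seqid}.match{counters[seqid]}"

    for p in doc.proteins:
        for xref in p.xrefs:
            fasta.append((xref.id, p.residues))
            if xref.orf is not None:
                o = xref.orf
                orf_lines.append((
                    o.parent_id, o.nt_start, o.nt_end,
                    f"{o.parent_id}\tsigscan\tORF\t{o.nt_start}\t{o.nt_end}"
                    f"\t.\t{o.strand}\t.\tID={_gff_escape(xref.id)}"))
            for am in p.matches:
                entry_acc = am.entry.accession if am.entry else None
                for loc in am.match.locations:
                    score = "." if loc.score is None else f"{loc.score:.3f}"
                    attrs = (f"ID={_gff_escape(next_id(xref.id))};"
                             f"signature={_gff_escape(am.match.signature_accession)};"
                             f"analysis={_gff_escape(am.analysis)}")
                    if entry_acc:
                        attrs += f";entry={_gff_escape(entry_acc)}"
                    prot_lines.append((
                        xref.id, am.analysis, am.match.signature_accession,
                        loc.start,
                        f"{xref.id}\t{am.analysis}\tprotein_match\t"
                        f"{loc.start}\t{loc.stop}\t{score}\t.\t.\t{attrs}"))
                    if xref.orf is not None:
                        orf = _orf_for(p, xref.orf)
                        nt_s, nt_e, strand = map_to_nucleotide(
                            orf, loc.start, loc.stop)
                        pattrs = (f"signature="
                                  f"{_gff_escape(am.match.signature_accession)};"
                                  f"analysis={_gff_escape(am.analysis)};"
                                  f"orf={_gff_escape(xref.id)}")
                        if entry_acc:
                            pattrs += f";entry={_gff_escape(entry_acc)}"
                        proj_lines.append((
                            xref.orf.parent_id, nt_s, nt_e, am.analysis,
                            am.match.signature_accession,
                            f"{xref.orf.parent_id}\t{am.analysis}\t"
                            f"protein_match\t{nt_s}\t{nt_e}\t{score}\t"
                            f"{strand}\t.\t{pattrs}"))
    for key in sorted(set(orf_lines)):
        lines.append(key[-1])
    for key in sorted(proj_lines):
        lines.append(key[-1])
    for key in sorted(prot_lines):
        lines.append(key[-1])
    lines.append("##FASTA")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for rid, residues in sorted(set(fasta)):
            fh.write(f">{rid}\n")
            for i in range(0, len(residues), 60):
                fh.write(residues[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# JSON (structural mirror of the XML)

def _doc_to_jsonable(doc: ResultDocument) -> dict:
    def entry_d(e: Optional[Entry]):
        if e is None:
            return None
        return {"accession": e.accession, "name": e.name, "type": e.type,
                "signatures": sorted(e.signature_accessions),
                "go_terms": [{"id": g.go_id, "category": g.category,
                              "term": g.term} for g in sorted(e.go_terms)],
                "pathways": [{"database": p.database, "id": p.pathway_id,
                              "name": p.name}
                             for p in sorted(e.pathway_xrefs)]}

    return {
        "tool_version": doc.tool_version,
        "date": doc.date,
        "analyses": [{"name": n, "version": v} for n, v in doc.analyses],
        "nucleotides": [{"id": n.id, "length": n.length,
                         "sequence": n.residues} for n in doc.nucleotides],
        "proteins": [{
            "md5": p.md5, "length": p.length, "sequence": p.residues,
            "xrefs": [
                {"id": x.id} if x.orf is None else
                {"id": x.id, "orf": {"parent": x.orf.parent_id,
                                     "strand": x.orf.strand,
                                     "nt_start": x.orf.nt_start,
                                     "nt_end": x.orf.nt_end}}
                for x in p.xrefs],
            "matches": [{
                "analysis": am.analysis,
                "signature": am.match.signature_accession,
                "signature_name": am.signature_name,
                "status": am.match.status,
                "entry": entry_d(am.entry),
                "locations": [
                    {"start": l.start, "stop": l.stop,
                     **({"score": l.score} if l.score is not None else {}),
                     **({"evalue": l.evalue} if l.evalue is not None else {})}
                    for l in am.match.locations]}
                for am in p.matches]}
            for p in doc.proteins],
    }


def write_json(doc: ResultDocument, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(_doc_to_jsonable(doc), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# convert

_WRITERS = {"tsv": write_tsv, "gff3": write_gff3, "json": write_json,
            "xml": write_xml}
UNSUPPORTED_TARGETS = {"html", "svg", "raw"}


def convert(xml_path: str, target: str, out_path: str) -> None:
    """Regenerate any output format from a stored canonical XML file.

    Byte-identical to writing the target directly from the in-memory
    document that produced the XML.
    """
    target = target.lower()
    if target in UNSUPPORTED_TARGETS:
        raise ValueError(
            f"conversion target {target!r} is not supported by this tool; "
            f"choose one of {sorted(_WRITERS)}")
    if target not in _WRITERS:
        raise ValueError(
            f"unknown conversion target {target!r}; "
            f"choose one of {sorted(_WRITERS)}")
    doc = read_xml(xml_path)
    _WRITERS[target](doc, out_path)
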