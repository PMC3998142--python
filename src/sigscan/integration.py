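"""Entry, GO-term and pathway annotation of filtered matches.

Signatures describing the same family, domain or site are grouped into
one curated entry; entries carry Gene Ontology terms and pathway
cross-references (KEGG, MetaCyc, UniPathway, plus Enzyme Commission
numbers carried in the same form).  Annotation is a pure lookup: no
match is filtered or altered here.

The pathway–entry association is determined automatically from a
reference annotation table (emulating a reference proteome): a pathway
is associated with an entry when a *significant proportion* — strictly
more than 80% — of the distinct proteins matched by that entry are
annotated with the pathway.  The rule normally runs at bundle-build
time, producing ``Entry.pathway_xrefs``; :func:`associate_pathways`
exposes the same computation at run time.

Bundle layout on disk (plain-text tables under one directory)::

    entries.tsv          accession  name  type
    signature_entry.tsv  signature_accession  entry_accession
    entry_go.tsv         entry_accession  go_id  category  term
    entry_pathway.tsv    entry_accession  database  pathway_id  name
    protein_pathway.tsv  protein_md5  database  pathway_id  name
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

from .model import (FILTERED_IN, Entry, GoTerm, Match, PathwayXref)

ASSOCIATION_THRESHOLD = 0.80  # strict: fraction must exceed this


@dataclass
class IntegrationBundle:
    entries: List[Entry]
    signature_to_entry: Dict[str, str]
    protein_pathway_annotations: Dict[str, Set[PathwayXref]]

    def __post_init__(self):
        by_acc = {e.accession: e for e in self.entries}
        if len(by_acc) != len(self.entries):
            raise ValueError("duplicate entry accession")
        for sig, ent in self.signature_to_entry.items():
            if ent not in by_acc:
                raise ValueError(
                    f"signature {sig} mapped to unknown entry {ent}")
        self._by_acc = by_acc

    def entry_for_signature(self, signature_accession: str) -> Optional[Entry]:
        acc = self.signature_to_entry.get(signature_accession)
        return self._by_acc.get(acc) if acc else None

    def entry(self, accession: str) -> Entry:
        return self._by_acc[accession]


@dataclass(frozen=True)
class AnnotatedMatch:
    """A filtered-in match decorated with its entry, GO terms and
    pathways (all empty for an unintegrated signature), plus the
    analysis name and signature description needed for output."""

    match: Match
    analysis: str
    signature_name: str
    entry: Optional[Entry] = None
    go_terms: frozenset = frozenset()
    pathways: frozenset = frozenset()


def annotate(matches: Sequence[Match], bundle: IntegrationBundle,
             analysis_names: Mapping[str, str],
             signature_names: Mapping[str, str]) -> List[AnnotatedMatch]:
    """Attach entry/GO/pathway annotation to filtered-in matches.

    *analysis_names* / *signature_names* map signature accession to the
    library name and signature description.  Pure lookup: conserves
    match count and never alters the matches themselves.
    """
    out = []
    for m in matches:
        if m.status != FILTERED_IN:
            raise ValueError(
                f"annotate expects filtered_in matches, got {m.status}")
        entry = bundle.entry_for_signature(m.signature_accession)
        go = entry.go_terms if entry else frozenset()
        pw = entry.pathway_xrefs if entry else frozenset()
        out.append(AnnotatedMatch(
            match=m,
            analysis=analysis_names.get(m.signature_accession, "-"),
            signature_name=signature_names.get(m.signature_accession, "-"),
            entry=entry, go_terms=go, pathways=pw))
    return out


def associate_pathways(entry: Entry, matched_proteins: Iterable[str],
                       bundle: IntegrationBundle) -> Set[PathwayXref]:
    """Pathways associated with *entry* under the strict >80% rule.

    A candidate pathway (any xref annotated on at least one matched
    protein) is associated iff the fraction of distinct matched
    proteins carrying it strictly exceeds 0.80.  An empty matched set
    yields an empty result.
    """
    md5s = set(matched_proteins)
    if not md5s:
        return set()
    counts: Dict[PathwayXref, int] = {}
    for md5 in md5s:
        for xref in bundle.protein_pathway_annotations.get(md5, ()):
            counts[xref] = counts.get(xref, 0) + 1
    n = len(md5s)
    return {xref for xref, c in counts.items()
            if c / n > ASSOCIATION_THRESHOLD}


def build_pathway_xrefs(bundle: IntegrationBundle,
                        entry_matches: Mapping[str, Iterable[str]]
                        ) -> Dict[str, Set[PathwayXref]]:
    """Apply the association rule for every entry at bundle-build time.

    *entry_matches* maps entry accession to the md5s of reference
    proteins matched by that entry.
    """
    return {acc: associate_pathways(bundle.entry(acc), md5s, bundle)
            for acc, md5s in entry_matches.items()}


# ---------------------------------------------------------------------------
# disk layout

def _read_tsv(path: str, ncols: int):
    rows = []
    if not os.path.exists(path):
        return rows
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != ncols:
                raise ValueError(
                    f"{path}:{lineno}: expected {ncols} fields, "
                    f"got {len(fields)}")
            rows.append(fields)
    return rows


def load_bundle(dirpath: str) -> IntegrationBundle:
    go_by_entry: Dict[str, set] = {}
    for acc, go_id, cat, term in _read_tsv(
            os.path.join(dirpath, "entry_go.tsv"), 4):
        go_by_entry.setdefault(acc, set()).add(
            GoTerm(go_id=go_id, category=cat, term=term))
    pw_by_entry: Dict[str, set] = {}
    for acc, db, pid, name in _read_tsv(
            os.path.join(dirpath, "entry_pathway.tsv"), 4):
        pw_by_entry.setdefault(acc, set()).add(
            PathwayXref(database=db, pathway_id=pid, name=name))
    sig_to_entry: Dict[str, str] = {}
    sigs_by_entry: Dict[str, set] = {}
    for sig, ent in _read_tsv(
            os.path.join(dirpath, "signature_entry.tsv"), 2):
        if sig in sig_to_entry:
            raise ValueError(f"signature {sig} mapped to more than one entry")
        sig_to_entry[sig] = ent
        sigs_by_entry.setdefault(ent, set()).add(sig)
    entries = []
    for acc, name, etype in _read_tsv(
            os.path.join(dirpath, "entries.tsv"), 3):
        entries.append(Entry(
            accession=acc, name=name, type=etype,
            signature_accessions=frozenset(sigs_by_entry.get(acc, ())),
            go_terms=frozenset(go_by_entry.get(acc, ())),
            pathway_xrefs=frozenset(pw_by_entry.get(acc, ()))))
    annotations: Dict[str, Set[PathwayXref]] = {}
    for md5, db, pid, name in _read_tsv(
            os.path.join(dirpath, "protein_pathway.tsv"), 4):
        annotations.setdefault(md5, set()).add(
            PathwayXref(database=db, pathway_id=pid, name=name))
    return IntegrationBundle(entries=entries, signature_to_entry=sig_to_entry,
                             protein_pathway_annotations=annotations)


def write_bundle(bundle: IntegrationBundle, dirpath: str) -> None:
    os.makedirs(dirpath, exist_ok=True)
    with open(os.path.join(dirpath, "entries.tsv"), "w") as fh:
        for e in sorted(bundle.entries, key=lambda e: e.accession):
            fh.write(f"{e.accession}\t{e.name}\t{e.type}\n")
    with open(os.path.join(dirpath, "signature_entry.tsv"), "w") as fh:
        for sig in sorted(bundle.signature_to_entry):
            fh.write(f"{sig}\t{bundle.signature_to_entry[sig]}\n")
    with open(os.path.join(dirpath, "entry_go.tsv"), "w") as fh:
        for e in sorted(bundle.entries, key=lambda e: e.accession):
            for g in sorted(e.go_terms):
                fh.write(f"{e.accession}\t{g.go_id}\t{g.category}\t{g.term}\n")
    with open(os.path.join(dirpath, "entry_pathway.tsv"), "w") as fh:
        for e in sorted(bundle.entries, key=lambda e: e.accession):
            for p in sorted(e.pathway_xrefs):
                fh.write(f"{e.accession}\t{p.database}\t{p.pathway_id}\t"
                         f"{p.name}\n")
    with open(os.path.join(dirpath, "protein_pathway.tsv"), "w") as fh:
        for md5 in sorted(bundle.protein_pathway_annotations):
            for p in sorted(bundle.protein_pathway_annotations[md5]):
                fh.write(f"{md5}\t{p.database}\t{p.pathway_id}\t{p.name}\n")
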