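"""Shared data model for the scanning framework.

Every other module builds on the value types defined here: validated
sequences with stable checksums, signatures and the curated entries that
group them, and matches (a signature's hit on one protein, with one or
more located regions).

Proteins are identified internally by the MD5 hex digest of their
canonical (uppercase, stop-stripped) residue string, so identical
sequences submitted under different identifiers are analyzed once and
results are fanned back out to every identifier.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XBZUO")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

_WS = re.compile(r"\s+")


class SequenceError(ValueError):
    """Raised when an input sequence fails validation.

    Carries the offending record identifier and, for alphabet
    violations, the illegal character and its 1-based position in the
    canonical (whitespace-stripped, uppercased) residue string.
    """

    def __init__(self, seq_id: str, message: str,
                 char: Optional[str] = None, position: Optional[int] = None):
        super().__init__(f"sequence {seq_id!r}: {message}")
        self.seq_id = seq_id
        self.char = char
        self.position = position


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence with a content-addressed checksum."""

    id: str
    residues: str
    md5: str
    length: int


@dataclass(frozen=True)
class NucleotideSequence:
    id: str
    residues: str
    length: int


@dataclass(frozen=True)
class OpenReadingFrame:
    """A stop-free codon run on one strand of a nucleotide sequence.

    Coordinates are 1-based inclusive on the forward strand regardless
    of the ORF strand.  The terminating stop codon, when present, is
    included in the nucleotide span but excluded from the translated
    protein.
    """

    parent_id: str
    strand: str  # '+' or '-'
    nt_start: int
    nt_end: int
    protein: ProteinSequence
    has_stop: bool = True


@dataclass(frozen=True)
class Signature:
    """A predictive model from a signature library release."""

    accession: str
    name: str
    library: str
    library_version: str
    model_kind: str  # 'pattern' | 'profile'
    model_payload: object
    clan: Optional[str] = None


@dataclass(frozen=True, order=True)
class PathwayXref:
    database: str  # e.g. KEGG, MetaCyc, UniPathway, EC
    pathway_id: str
    name: str = ""

    @property
    def key(self) -> str:
        return f"{self.database}:{self.pathway_id}"


@dataclass(frozen=True, order=True)
class GoTerm:
    go_id: str
    category: str = ""
    term: str = ""


@dataclass(frozen=True)
class Entry:
    """A curated entry grouping signatures that describe the same
    family, domain, site or repeat, with GO and pathway cross-refs."""

    accession: str
    name: str
    type: str  # family | domain | site | repeat
    signature_accessions: frozenset = frozenset()
    go_terms: frozenset = frozenset()      # of GoTerm
    pathway_xrefs: frozenset = frozenset() # of PathwayXref


@dataclass(frozen=True, order=True)
class Location:
    """One located region of a match, 1-based inclusive on the protein."""

    start: int
    stop: int
    score: Optional[float] = None
    evalue: Optional[float] = None

    def __post_init__(self):
        if not (1 <= self.start <= self.stop):
            raise ValueError(f"invalid location {self.start}..{self.stop}")


# match statuses
RAW = "raw"
FILTERED_IN = "filtered_in"
FILTERED_OUT = "filtered_out"


@dataclass(frozen=True)
class Match:
    """One signature's hit on one protein (≥1 located region).

    Only ``filtered_in`` matches appear in user-facing output; the
    analyzer post-processing stage sets the status, never the scanner.
    """

    protein_md5: str
    signature_accession: str
    locations: tuple  # tuple[Location, ...], nonempty
    status: str = RAW

    def __post_init__(self):
        if not self.locations:
            raise ValueError("match requires at least one location")

    def with_status(self, status: str) -> "Match":
        return replace(self, status=status)

    def sort_key(self):
        return (self.protein_md5, self.signature_accession,
                self.locations[0].start, self.locations[0].stop)


# ---------------------------------------------------------------------------
# serialization helpers (used by the lookup store and the job engine,
# which pass matches across process boundaries as JSON)

def location_to_dict(loc: Location) -> dict:
    d = {"start": loc.start, "stop": loc.stop}
    if loc.score is not None:
        d["score"] = loc.score
    if loc.evalue is not None:
        d["evalue"] = loc.evalue
    return d


def location_from_dict(d: Mapping) -> Location:
    return Location(start=int(d["start"]), stop=int(d["stop"]),
                    score=d.get("score"), evalue=d.get("evalue"))


def match_to_dict(m: Match) -> dict:
    return {
        "protein_md5": m.protein_md5,
        "signature_accession": m.signature_accession,
        "status": m.status,
        "locations": [location_to_dict(l) for l in m.locations],
    }


def match_from_dict(d: Mapping) -> Match:
    return Match(
        protein_md5=d["protein_md5"],
        signature_accession=d["signature_accession"],
        status=d.get("status", RAW),
        locations=tuple(location_from_dict(l) for l in d["locations"]),
    )


# ---------------------------------------------------------------------------
# canonicalization / checksumming

def canonicalize_and_checksum(raw_id: str, raw_residues: str) -> ProteinSequence:
    """Validate and canonicalize a raw residue string, returning a
    :class:`ProteinSequence` whose ``md5`` is the lowercase MD5 hex
    digest of the canonical residues.

    Canonical form: whitespace removed, uppercased, trailing stop
    characters (``*``) stripped.  An internal ``*`` or any character
    outside the accepted amino-acid alphabet (20 standard residues plus
    B, Z, X, U, O) is an error naming the character and its 1-based
    position.  The checksum is a pure function of the canonical
    residues: the identifier and the original case never affect it.
    """
    residues = _WS.sub("", raw_residues).upper()
    residues = residues.rstrip("*")
    if not residues:
        raise SequenceError(raw_id, "empty sequence")
    for pos, ch in enumerate(residues, start=1):
        if ch not in PROTEIN_ALPHABET:
            raise SequenceError(
                raw_id,
                f"illegal character {ch!r} at position {pos}",
                char=ch, position=pos)
    md5 = hashlib.md5(residues.encode("ascii")).hexdigest()
    return ProteinSequence(id=raw_id, residues=residues, md5=md5,
                           length=len(residues))


def canonicalize_nucleotide(raw_id: str, raw_residues: str) -> NucleotideSequence:
    """Validate a nucleotide string over {A,C,G,T,N}, uppercased."""
    residues = _WS.sub("", raw_residues).upper()
    if not residues:
        raise SequenceError(raw_id, "empty sequence")
    for pos, ch in enumerate(residues, start=1):
        if ch not in NUCLEOTIDE_ALPHABET:
            raise SequenceError(
                raw_id,
                f"illegal character {ch!r} at position {pos}",
                char=ch, position=pos)
    return NucleotideSequence(id=raw_id, residues=residues, length=len(residues))


def deduplicate(sequences: Sequence[ProteinSequence]):
    """Collapse identical sequences by checksum.

    Returns ``(unique, alias_map)`` where ``unique`` keeps the first
    occurrence of each distinct md5 in input order and ``alias_map``
    maps each md5 to every input identifier carrying that sequence.
    Downstream analysis runs once per md5; output is fanned back out to
    every identifier.
    """
    unique: list[ProteinSequence] = []
    alias_map: dict[str, list[str]] = {}
    for seq in sequences:
        if seq.md5 not in alias_map:
            alias_map[seq.md5] = []
            unique.append(seq)
        alias_map[seq.md5].append(seq.id)
    return unique, alias_map
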