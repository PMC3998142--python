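"""Built-in sequence analyzers and the contract they implement.

Signature-scanning applications come in two modalities: single-pass
predictors whose raw output is final (an identity post-process), and
multi-model scanners whose raw hits are filtered by a post-processing
step before results are reported.  Both are represented here behind one
:class:`AnalyzerContract`; the bundled implementations are deliberately
lightweight models (PROSITE-style patterns and position-weight
profiles) so that the framework is fully exercisable without any
external scan binaries.  Adapters for external binaries would implement
the same contract.

Pattern repeat semantics: for each distinct start position the scanner
reports the *shortest* accepting window (variable-count elements take
as few residues as possible).  This is a documented convention, tested
against a brute-force expansion oracle.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .model import (FILTERED_IN, FILTERED_OUT, RAW, Location, Match,
                    ProteinSequence, Signature)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA20)}


class PatternSyntaxError(ValueError):
    """Malformed pattern; carries the character position of the fault."""

    def __init__(self, pattern: str, position: int, message: str):
        super().__init__(
            f"pattern {pattern!r}: {message} at position {position}")
        self.pattern = pattern
        self.position = position


@dataclass(frozen=True)
class PatternElement:
    """One pattern element: a residue set repeated min..max times.

    ``charset`` is None for the 'x' wildcard (any residue).
    """

    charset: Optional[frozenset]
    min_count: int = 1
    max_count: int = 1
    negated: bool = False

    def accepts(self, ch: str) -> bool:
        if self.charset is None:
            return True
        return (ch not in self.charset) if self.negated else (ch in self.charset)


@dataclass(frozen=True)
class PatternModel:
    """A parsed PROSITE-style pattern.

    Supported syntax: residue literals, ``x`` wildcard, ``[SET]``,
    ``{NEGATED}``, fixed ``(n)`` and ranged ``(n,m)`` repeats, and the
    terminal anchors ``<`` (N-terminus) and ``>`` (C-terminus).  No
    nested groups.
    """

    pattern: str
    elements: Tuple[PatternElement, ...]
    anchored_start: bool = False
    anchored_end: bool = False

    @property
    def min_length(self) -> int:
        return sum(e.min_count for e in self.elements)


_REPEAT = re.compile(r"\((\d+)(?:,(\d+))?\)")


def parse_pattern(pattern: str) -> PatternModel:
    """Parse a PROSITE-style pattern string into a :class:`PatternModel`."""
    text = pattern.rstrip(".")
    anchored_start = anchored_end = False
    i = 0
    if text.startswith("<"):
        anchored_start = True
        i = 1
    body = text
    if body.endswith(">"):
        anchored_end = True
        body = body[:-1]
    elements: list[PatternElement] = []
    while i < len(body):
        ch = body[i]
        if ch == "-":
            i += 1
            continue
        charset: Optional[frozenset]
        negated = False
        if ch == "x":
            charset = None
            i += 1
        elif ch in "[{":
            closer = "]" if ch == "[" else "}"
            end = body.find(closer, i)
            if end < 0:
                raise PatternSyntaxError(pattern, i, f"unclosed {ch!r}")
            members = body[i + 1:end]
            if not members or any(c not in AA20 + "XBZUO" for c in members):
                raise PatternSyntaxError(pattern, i, "invalid residue set")
            charset = frozenset(members)
            negated = ch == "{"
            i = end + 1
        elif ch.isalpha() and ch.upper() in AA20 + "XBZUO":
            charset = frozenset(ch.upper())
            i += 1
        else:
            raise PatternSyntaxError(pattern, i, f"unexpected character {ch!r}")
        mn = mx = 1
        m = _REPEAT.match(body, i)
        if m:
            mn = int(m.group(1))
            mx = int(m.group(2)) if m.group(2) else mn
            if mx < mn:
                raise PatternSyntaxError(pattern, i, "max repeat below min")
            i = m.end()
        elements.append(PatternElement(charset=charset, min_count=mn,
                                       max_count=mx, negated=negated))
    if not elements:
        raise PatternSyntaxError(pattern, 0, "empty pattern")
    return PatternModel(pattern=pattern, elements=tuple(elements),
                        anchored_start=anchored_start,
                        anchored_end=anchored_end)


def _shortest_match_end(seq: str, start: int, model: PatternModel) -> Optional[int]:
    """Dynamic program over element index: the set of end offsets
    reachable after consuming each element, keeping minimality exact."""
    n = len(seq)
    reachable = {start}
    for elem in model.elements:
        nxt: set[int] = set()
        for pos in reachable:
            # consume min_count..max_count accepted residues from pos
            p = pos
            ok = True
            for k in range(elem.min_count):
                if p >= n or not elem.accepts(seq[p]):
                    ok = False
                    break
                p += 1
            if not ok:
                continue
            nxt.add(p)
            for k in range(elem.max_count - elem.min_count):
                if p >= n or not elem.accepts(seq[p]):
                    break
                p += 1
                nxt.add(p)
        if not nxt:
            return None
        reachable = nxt
    # a zero-length acceptance (all elements optional) is not a match
    if model.anchored_end:
        return n if (n in reachable and n > start) else None
    candidates = [p for p in reachable if p > start]
    return min(candidates) if candidates else None


def scan_pattern(protein: ProteinSequence, model: PatternModel) -> List[Location]:
    """Report every distinct start position at which *model* accepts,
    with its shortest accepting window, in leftmost order.

    Overlapping occurrences at distinct starts are all reported; scores
    are absent (patterns are binary predictors).
    """
    seq = protein.residues
    starts = [0] if model.anchored_start else range(len(seq))
    out = []
    for s in starts:
        end = _shortest_match_end(seq, s, model)
        if end is not None and end > s:
            out.append(Location(start=s + 1, stop=end))
    return out


@dataclass(frozen=True)
class ProfileModel:
    """A position-weight profile: per-position scores for each of the 20
    standard residues; residues outside that alphabet score 0.  A
    length-L window is a hit when its summed score reaches *threshold*.
    """

    matrix: np.ndarray  # shape (L, 20), float
    threshold: float

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 20 or m.shape[0] < 1:
            raise ValueError("profile matrix must be (L, 20) with L >= 1")
        if not np.all(np.isfinite(m)):
            raise ValueError("profile matrix must be finite")
        object.__setattr__(self, "matrix", m)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


def scan_profile(protein: ProteinSequence, model: ProfileModel) -> List[Location]:
    """Score every length-L window of *protein* against the profile and
    report each window with summed score ≥ threshold.

    Non-maximal overlapping windows are retained at this raw stage;
    filtering is the post-processor's job.  A protein shorter than L
    yields an empty result.
    """
    L = model.length
    n = protein.length
    if n < L:
        return []
    idx = np.array([_AA_INDEX.get(ch, -1) for ch in protein.residues])
    # window sums: sum over i of matrix[i, seq[j+i]]; unknown residues score 0
    scores = np.zeros(n - L + 1)
    for i in range(L):
        seg = idx[i:i + n - L + 1]
        col = model.matrix[i]
        vals = np.where(seg >= 0, col[np.clip(seg, 0, 19)], 0.0)
        scores += vals
    out = []
    for j, sc in enumerate(scores):
        if sc >= model.threshold:
            out.append(Location(start=j + 1, stop=j + L, score=float(sc)))
    return out


# ---------------------------------------------------------------------------
# post-processing

def _loc_rank(sig_acc: str, loc: Location):
    # higher score first; scoreless locations rank below any scored one
    score = loc.score if loc.score is not None else float("-inf")
    return (-score, loc.start, sig_acc)


def resolve_overlaps(matches: Sequence[Match],
                     signatures: Dict[str, Signature]) -> List[Match]:
    """Clan-style overlap filtering on one protein's matches.

    Within each clan, locations that overlap by at least one residue
    compete and only the best survives: highest location score, then
    smaller start, then lexicographically smaller signature accession.
    A multi-location match competes location-wise and survives if any
    of its locations survives.  Clanless matches always survive.  No
    match is removed — statuses become ``filtered_in``/``filtered_out``.
    """
    if not matches:
        return []
    md5s = {m.protein_md5 for m in matches}
    if len(md5s) > 1:
        raise ValueError("resolve_overlaps expects matches on one protein")

    survivors: dict[int, bool] = {}
    by_clan: dict[str, list[tuple[int, Match]]] = {}
    for i, m in enumerate(matches):
        sig = signatures.get(m.signature_accession)
        clan = sig.clan if sig else None
        if clan is None:
            survivors[i] = True
        else:
            by_clan.setdefault(clan, []).append((i, m))

    for clan, members in by_clan.items():
        # greedy: best-ranked location claims its interval; a location
        # overlapping an already-kept interval loses
        cands = [(i, m.signature_accession, loc)
                 for i, m in members for loc in m.locations]
        cands.sort(key=lambda t: _loc_rank(t[1], t[2]))
        kept_intervals: list[tuple[int, int]] = []
        winner_idx: set[int] = set()
        for i, acc, loc in cands:
            if any(loc.start <= e and s <= loc.stop for s, e in kept_intervals):
                continue
            kept_intervals.append((loc.start, loc.stop))
            winner_idx.add(i)
        for i, m in members:
            survivors[i] = i in winner_idx

    return [m.with_status(FILTERED_IN if survivors[i] else FILTERED_OUT)
            for i, m in enumerate(matches)]


# ---------------------------------------------------------------------------
# analyzer contract

@dataclass
class AnalyzerContract:
    """One analysis application: a pure scan over (protein, signature)
    pairs plus a post-process that only sets match statuses."""

    name: str
    scan: Callable[[Sequence[ProteinSequence], Sequence[Signature]], List[Match]]
    postprocess: Callable[[Sequence[Match], Dict[str, Signature]], List[Match]]


def _scan_signatures(proteins: Sequence[ProteinSequence],
                     signatures: Sequence[Signature]) -> List[Match]:
    matches = []
    for prot in proteins:
        for sig in sorted(signatures, key=lambda s: s.accession):
            if sig.model_kind == "pattern":
                locs = scan_pattern(prot, sig.model_payload)
            elif sig.model_kind == "profile":
                locs = scan_profile(prot, sig.model_payload)
            else:
                raise ValueError(f"unknown model kind {sig.model_kind!r}")
            if locs:
                matches.append(Match(protein_md5=prot.md5,
                                     signature_accession=sig.accession,
                                     locations=tuple(locs), status=RAW))
    return matches


def _clan_postprocess(matches: Sequence[Match],
                      signatures: Dict[str, Signature]) -> List[Match]:
    by_prot: dict[str, list[Match]] = {}
    for m in matches:
        by_prot.setdefault(m.protein_md5, []).append(m)
    out = []
    for md5 in sorted(by_prot):
        out.extend(resolve_overlaps(by_prot[md5], signatures))
    return out


def _identity_postprocess(matches: Sequence[Match],
                          signatures: Dict[str, Signature]) -> List[Match]:
    return [m.with_status(FILTERED_IN) for m in matches]


def scan_filter_analyzer(name: str) -> AnalyzerContract:
    """Multi-model modality: scan, then clan-overlap post-processing."""
    return AnalyzerContract(name=name, scan=_scan_signatures,
                            postprocess=_clan_postprocess)


def single_pass_analyzer(name: str) -> AnalyzerContract:
    """Single-algorithm modality: raw output is final (identity
    post-process, everything filtered in)."""
    return AnalyzerContract(name=name, scan=_scan_signatures,
                            postprocess=_identity_postprocess)


MODALITIES = {
    "scan_filter": scan_filter_analyzer,
    "single_pass": single_pass_analyzer,
}


def run_analysis(proteins: Sequence[ProteinSequence],
                 signatures: Sequence[Signature],
                 contract: AnalyzerContract) -> List[Match]:
    """Run one analysis end to end: scan, post-process, return matches
    in canonical order.  Deterministic given its inputs."""
    libs = {s.library for s in signatures}
    if len(libs) > 1:
        raise ValueError("signatures must come from a single library release")
    sig_index = {s.accession: s for s in signatures}
    raw = contract.scan(proteins, signatures)
    processed = contract.postprocess(raw, sig_index)
    return sorted(processed, key=Match.sort_key)
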