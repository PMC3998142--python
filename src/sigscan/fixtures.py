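"""Synthetic fixtures with known ground truth.

Generates everything a run needs — protein (or nucleotide) FASTA with
planted motif occurrences, a toy signature library release, and an
integration bundle with entries, GO terms and pathway annotation —
purely from a seed, so identical specs produce byte-identical files.

Background residues are drawn uniformly from the 20-residue alphabet
and *rejection-sampled*: a candidate protein is regenerated until
scanning it against every library model yields exactly the planted
occurrences, so recall and precision against the recorded ground truth
are exact by construction, not probabilistically.

The bundled toy library (``TOYLIB`` release 1.0) has four signatures —
two patterns in one clan, a clanless pattern, a position-weight
profile — grouped under two entries plus one deliberately
unintegrated signature.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from Bio.Seq import Seq

from .analyzers import AA20, parse_pattern, scan_pattern, scan_profile, \
    ProfileModel
from .integration import (IntegrationBundle, associate_pathways,
                          write_bundle)
from .library import LibraryRelease, write_library
from .model import (Entry, GoTerm, PathwayXref, ProteinSequence, Signature,
                    canonicalize_and_checksum)

LIBRARY_NAME = "TOYLIB"
LIBRARY_VERSION = "1.0"

_PROFILE_CONSENSUS = "WKWHW"
_PROFILE_SCORE = 6.0
_PROFILE_THRESHOLD = 30.0  # only the exact consensus window reaches it


def toy_library() -> LibraryRelease:
    """The standard toy signature library release."""
    matrix = np.zeros((len(_PROFILE_CONSENSUS), 20))
    for i, aa in enumerate(_PROFILE_CONSENSUS):
        matrix[i, AA20.index(aa)] = _PROFILE_SCORE
    sigs = [
        Signature("TOY00001", "zinc-knuckle-like pattern", LIBRARY_NAME,
                  LIBRARY_VERSION, "pattern",
                  parse_pattern("C-x(2)-C-H"), clan="CL0001"),
        Signature("TOY00002", "acidic kinase-site pattern", LIBRARY_NAME,
                  LIBRARY_VERSION, "pattern",
                  parse_pattern("[DE](2)-K-x-[ST]"), clan=None),
        Signature("TOY00003", "tryptophan-rich profile", LIBRARY_NAME,
                  LIBRARY_VERSION, "profile",
                  ProfileModel(matrix=matrix, threshold=_PROFILE_THRESHOLD),
                  clan="CL0001"),
        Signature("TOY00004", "loose glycine loop pattern", LIBRARY_NAME,
                  LIBRARY_VERSION, "pattern",
                  parse_pattern("G-x(1,3)-G-K-[ST]"), clan=None),
    ]
    return LibraryRelease(name=LIBRARY_NAME, version=LIBRARY_VERSION,
                          modality="scan_filter", signatures=sigs)


@dataclass(frozen=True)
class Placement:
    protein_index: int
    signature_accession: str
    position: int  # 1-based residue position of the planted occurrence


@dataclass
class FixtureSpec:
    seed: int = 1
    n_proteins: int = 50
    min_length: int = 80
    max_length: int = 140
    placements: Optional[List[Placement]] = None  # None = default layout
    n_placements: int = 10
    # fraction of each entry's matched reference proteins annotated with
    # its candidate pathway (probes the strict >80% association rule)
    pathway_fractions: Dict[str, float] = field(
        default_factory=lambda: {"ENT00001": 0.9, "ENT00002": 0.8})
    max_rejections: int = 500


@dataclass
class GroundTruth:
    """Everything the generated data is guaranteed to contain."""

    matches: List[dict]            # protein_id, md5, analysis, signature, start, stop
    pathway_expected: List[dict]   # entry, database, pathway_id, associated
    nucleotide: List[dict] = field(default_factory=list)
    # contig, orf_strand, orf_nt_start, orf_nt_end, signature, nt_start, nt_end


def _realize_pattern(pattern_str: str, rng: random.Random) -> str:
    """A concrete string matching the pattern at its minimal length."""
    model = parse_pattern(pattern_str)
    out = []
    for elem in model.elements:
        for _ in range(elem.min_count):
            if elem.charset is None:
                out.append(rng.choice(AA20))
            elif elem.negated:
                out.append(rng.choice([a for a in AA20
                                       if a not in elem.charset]))
            else:
                out.append(rng.choice(sorted(elem.charset)))
    return "".join(out)


def _instance_for(sig: Signature, rng: random.Random) -> str:
    if sig.model_kind == "pattern":
        return _realize_pattern(sig.model_payload.pattern, rng)
    return _PROFILE_CONSENSUS


def _scan_all(protein: ProteinSequence, library: LibraryRelease):
    found = []
    for sig in library.signatures:
        if sig.model_kind == "pattern":
            locs = scan_pattern(protein, sig.model_payload)
        else:
            locs = scan_profile(protein, sig.model_payload)
        for loc in locs:
            found.append((sig.accession, loc.start, loc.stop))
    return sorted(found)


def _default_placements(spec: FixtureSpec,
                        library: LibraryRelease) -> List[Placement]:
    accs = [s.accession for s in library.signatures]
    placements = []
    for k in range(spec.n_placements):
        placements.append(Placement(
            protein_index=k % spec.n_proteins,
            signature_accession=accs[k % len(accs)],
            position=0))  # 0 = auto-position
    return placements


def _build_protein(idx: int, length: int, placements: List[Placement],
                   library: LibraryRelease, rng: random.Random,
                   max_rejections: int) -> Tuple[ProteinSequence, List[dict]]:
    sig_by_acc = library.signature_index()
    # realize planted instances once so ground truth is fixed
    planted = []
    cursor = 5
    for pl in placements:
        inst = _instance_for(sig_by_acc[pl.signature_accession], rng)
        pos = pl.position or cursor
        cursor = pos + len(inst) + 7  # keep placements well separated
        planted.append((pl.signature_accession, pos, inst))
    need = max((pos + len(inst) for _, pos, inst in planted), default=0)
    length = max(length, need + 5)

    expected = sorted((acc, pos, pos + len(inst) - 1)
                      for acc, pos, inst in planted)
    for _ in range(max_rejections):
        residues = [rng.choice(AA20) for _ in range(length)]
        for acc, pos, inst in planted:
            residues[pos - 1:pos - 1 + len(inst)] = inst
        prot = canonicalize_and_checksum(f"prot_{idx:04d}", "".join(residues))
        if _scan_all(prot, library) == expected:
            rows = [{"protein_id": prot.id, "md5": prot.md5,
                     "analysis": library.name, "signature": acc,
                     "start": pos, "stop": stop}
                    for acc, pos, stop in expected]
            return prot, rows
    raise RuntimeError(
        f"could not realize protein {idx} without spurious matches "
        f"after {max_rejections} attempts")


def _integration_tables(spec: FixtureSpec, library: LibraryRelease,
                        matches: List[dict], rng: random.Random):
    """Entries/GO tables plus pathway annotation engineered to the
    requested per-entry fractions; entry→pathway associations are the
    output of the >80% rule applied to those annotations."""
    entries = [
        Entry("ENT00001", "Toy zinc finger family", "family",
              signature_accessions=frozenset({"TOY00001", "TOY00002"}),
              go_terms=frozenset({
                  GoTerm("GO:0008270", "MF", "zinc ion binding"),
                  GoTerm("GO:0003677", "MF", "DNA binding")})),
        Entry("ENT00002", "Toy tryptophan-rich domain", "domain",
              signature_accessions=frozenset({"TOY00003"}),
              go_terms=frozenset({
                  GoTerm("GO:0005515", "MF", "protein binding")})),
    ]
    sig_to_entry = {"TOY00001": "ENT00001", "TOY00002": "ENT00001",
                    "TOY00003": "ENT00002"}  # TOY00004 left unintegrated
    candidates = {"ENT00001": PathwayXref("KEGG", "K00001",
                                          "toy biosynthesis"),
                  "ENT00002": PathwayXref("MetaCyc", "PWY-0002",
                                          "toy degradation")}

    matched_by_entry: Dict[str, set] = {e.accession: set() for e in entries}
    for row in matches:
        ent = sig_to_entry.get(row["signature"])
        if ent:
            matched_by_entry[ent].add(row["md5"])

    annotations: Dict[str, set] = {}
    pathway_expected = []
    for ent_acc, md5s in sorted(matched_by_entry.items()):
        frac = spec.pathway_fractions.get(ent_acc, 0.0)
        xref = candidates[ent_acc]
        md5s_sorted = sorted(md5s)
        n_annot = int(round(frac * len(md5s_sorted)))
        for md5 in md5s_sorted[:n_annot]:
            annotations.setdefault(md5, set()).add(xref)
        associated = (len(md5s_sorted) > 0 and
                      n_annot / len(md5s_sorted) > 0.80)
        pathway_expected.append({"entry": ent_acc, "database": xref.database,
                                 "pathway_id": xref.pathway_id,
                                 "associated": associated})

    bundle = IntegrationBundle(entries=entries,
                               signature_to_entry=sig_to_entry,
                               protein_pathway_annotations=annotations)
    # apply the association rule at bundle-build time
    final_entries = []
    for e in entries:
        xrefs = associate_pathways(e, matched_by_entry[e.accession], bundle)
        final_entries.append(Entry(
            accession=e.accession, name=e.name, type=e.type,
            signature_accessions=e.signature_accessions,
            go_terms=e.go_terms, pathway_xrefs=frozenset(xrefs)))
    bundle = IntegrationBundle(entries=final_entries,
                               signature_to_entry=sig_to_entry,
                               protein_pathway_annotations=annotations)
    return bundle, pathway_expected


def generate(spec: FixtureSpec, outdir: str
             ) -> Tuple[str, str, str, GroundTruth]:
    """Generate a complete protein fixture.

    Returns ``(fasta_path, data_dir, ground_truth_path, ground_truth)``
    where ``data_dir`` holds the library release and integration
    bundle in their documented layouts.
    """
    rng = random.Random(spec.seed)
    library = toy_library()
    placements = spec.placements or _default_placements(spec, library)
    by_protein: Dict[int, List[Placement]] = {}
    for pl in placements:
        if pl.protein_index >= spec.n_proteins:
            raise ValueError(
                f"placement on protein {pl.protein_index} but only "
                f"{spec.n_proteins} proteins requested")
        by_protein.setdefault(pl.protein_index, []).append(pl)

    proteins = []
    match_rows: List[dict] = []
    for idx in range(spec.n_proteins):
        length = rng.randint(spec.min_length, spec.max_length)
        prot, rows = _build_protein(idx, length, by_protein.get(idx, []),
                                    library, rng, spec.max_rejections)
        proteins.append(prot)
        match_rows.extend(rows)

    os.makedirs(outdir, exist_ok=True)
    fasta_path = os.path.join(outdir, "proteins.fasta")
    with open(fasta_path, "w") as fh:
        for prot in proteins:
            fh.write(f">{prot.id}\n")
            for i in range(0, prot.length, 60):
                fh.write(prot.residues[i:i + 60] + "\n")

    data_dir = os.path.join(outdir, "data")
    write_library(library, os.path.join(
        data_dir, "libraries", f"{library.name}-{library.version}"))
    bundle, pathway_expected = _integration_tables(spec, library,
                                                   match_rows, rng)
    write_bundle(bundle, os.path.join(data_dir, "integration"))

    gt = GroundTruth(matches=sorted(
        match_rows, key=lambda r: (r["protein_id"], r["signature"],
                                   r["start"])),
        pathway_expected=pathway_expected)
    gt_path = os.path.join(outdir, "ground_truth.tsv")
    with open(gt_path, "w") as fh:
        fh.write("# protein_id\tmd5\tanalysis\tsignature\tstart\tstop\n")
        for r in gt.matches:
            fh.write(f"{r['protein_id']}\t{r['md5']}\t{r['analysis']}\t"
                     f"{r['signature']}\t{r['start']}\t{r['stop']}\n")
        fh.write("# entry\tdatabase\tpathway_id\tassociated\n")
        for r in gt.pathway_expected:
            fh.write(f"{r['entry']}\t{r['database']}\t{r['pathway_id']}\t"
                     f"{int(r['associated'])}\n")
    return fasta_path, data_dir, gt_path, gt


# ---------------------------------------------------------------------------
# nucleotide fixtures

_CODONS = {}
for _b1 in "ACGT":
    for _b2 in "ACGT":
        for _b3 in "ACGT":
            _c = _b1 + _b2 + _b3
            _aa = str(Seq(_c).translate(table=1))
            _CODONS.setdefault(_aa, []).append(_c)


def _reverse_translate(residues: str, rng: random.Random) -> str:
    return "".join(rng.choice(_CODONS[aa]) for aa in residues)


def _random_nt(n: int, rng: random.Random) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def generate_nucleotide(spec: FixtureSpec, outdir: str,
                        strands: Optional[Sequence[str]] = None,
                        frames: Optional[Sequence[int]] = None,
                        min_protein_length: int = 20
                        ) -> Tuple[str, str, str, GroundTruth]:
    """Generate contigs embedding the planted proteins as ORFs.

    Each planted protein is reverse-translated into a coding sequence
    flanked by in-frame stop codons and embedded (on a random or
    requested strand/frame) in random nucleotide background, one contig
    per protein.  Ground truth records the expected ORF span and the
    nucleotide-projected coordinates of every planted match, computed
    arithmetically from the embedding (not via the coordinate mapper
    under test).
    """
    from .orfs import find_orfs  # verification only
    from .model import canonicalize_nucleotide

    rng = random.Random(spec.seed + 7919)
    library = toy_library()
    fasta_path, data_dir, _, gt = generate(spec, outdir)

    by_protein: Dict[str, List[dict]] = {}
    for row in gt.matches:
        by_protein.setdefault(row["protein_id"], []).append(row)
    # carry every generated protein into a contig; only planted matches
    # contribute ground truth
    prot_seqs = {}
    with open(fasta_path) as fh:
        rid, buf = None, []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if rid:
                    prot_seqs[rid] = "".join(buf)
                rid, buf = line[1:], []
            else:
                buf.append(line)
        if rid:
            prot_seqs[rid] = "".join(buf)

    contigs = []
    nt_truth: List[dict] = []
    items = sorted(prot_seqs.items())
    for j, (pid, residues) in enumerate(items):
        strand = (strands[j % len(strands)] if strands
                  else rng.choice("+-"))
        frame = (frames[j % len(frames)] if frames else rng.randrange(3))
        contig_id = f"contig_{j:04d}"
        for attempt in range(spec.max_rejections):
            cds = _reverse_translate(residues, rng)
            cassette = "TAA" + cds + "TAA"
            if strand == "-":
                cassette = str(Seq(cassette).reverse_complement())
            left_len = rng.randrange(10, 40)
            left_len += (frame - left_len) % 3
            left = _random_nt(left_len, rng)
            right = _random_nt(rng.randrange(10, 40), rng)
            contig = left + cassette + right
            p = len(left)  # 0-based cassette offset
            if strand == "+":
                orf_start = p + 4               # 1-based, first CDS base
                orf_end = p + 3 + len(cds) + 3  # includes the stop codon
            else:
                orf_start = p + len(cassette) - 5 - len(cds)
                orf_end = p + len(cassette) - 3
            nt = canonicalize_nucleotide(contig_id, contig)
            orfs = find_orfs(nt, min_protein_length)
            wanted = [o for o in orfs if o.strand == strand and
                      o.nt_start == orf_start and o.nt_end == orf_end and
                      o.protein.residues == residues]
            if not wanted:
                continue
            spurious = False
            for o in orfs:
                hits = _scan_all(o.protein, library)
                expected = (sorted((r["signature"], r["start"], r["stop"])
                                   for r in by_protein.get(pid, []))
                            if o.protein.residues == residues else [])
                if hits != expected:
                    spurious = True
                    break
            if not spurious:
                break
        else:
            raise RuntimeError(
                f"could not embed protein {pid} cleanly after "
                f"{spec.max_rejections} attempts")
        contigs.append((contig_id, contig))
        for r in by_protein.get(pid, []):
            if strand == "+":
                f_start = orf_start + 3 * (r["start"] - 1)
                f_end = orf_start + 3 * r["stop"] - 1
            else:
                f_end = orf_end - 3 * (r["start"] - 1)
                f_start = orf_end - 3 * r["stop"] + 1
            nt_truth.append({
                "contig": contig_id, "orf_strand": strand,
                "orf_nt_start": orf_start, "orf_nt_end": orf_end,
                "signature": r["signature"], "nt_start": f_start,
                "nt_end": f_end})

    nt_fasta = os.path.join(outdir, "contigs.fasta")
    with open(nt_fasta, "w") as fh:
        for cid, seq in contigs:
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    gt.nucleotide = sorted(
        nt_truth, key=lambda r: (r["contig"], r["signature"], r["nt_start"]))
    gt_path = os.path.join(outdir, "ground_truth_nt.tsv")
    with open(gt_path, "w") as fh:
        fh.write("# contig\torf_strand\torf_nt_start\torf_nt_end\t"
                 "signature\tnt_start\tnt_end\n")
        for r in gt.nucleotide:
            fh.write(f"{r['contig']}\t{r['orf_strand']}\t"
                     f"{r['orf_nt_start']}\t{r['orf_nt_end']}\t"
                     f"{r['signature']}\t{r['nt_start']}\t{r['nt_end']}\n")
    return nt_fasta, data_dir, gt_path, gt
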