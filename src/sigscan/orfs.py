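"""Six-frame ORF finding and protein→nucleotide coordinate back-mapping.

Nucleotide input is translated into ORF-derived proteins which are then
scanned like any other protein; features predicted in protein
coordinates are projected back onto the parent nucleotide sequence for
GFF3 output.

Conventions (getorf-style, documented rather than biology-mandated):

* ORFs are maximal stop-free codon runs in each of the six reading
  frames (stop-to-stop, not ATG-anchored).
* The terminating stop codon is included in the nucleotide span when
  present, but excluded from the translated protein.
* All coordinates are 1-based inclusive on the *forward* strand, for
  both strands.
* Standard genetic code (translation table 1) only.
"""

from __future__ import annotations

import hashlib
from typing import List, Tuple

from Bio.Seq import Seq

from .model import NucleotideSequence, OpenReadingFrame, ProteinSequence

DEFAULT_MIN_PROTEIN_LENGTH = 50

_STOPS = {"TAA", "TAG", "TGA"}


def _translate_codon(codon: str) -> str:
    if "N" in codon:
        return "X"
    return str(Seq(codon).translate(table=1))


def _protein_for(parent_id: str, strand: str, nt_start: int, nt_end: int,
                 residues: str) -> ProteinSequence:
    pid = f"{parent_id}_orf_{strand}_{nt_start}_{nt_end}"
    md5 = hashlib.md5(residues.encode("ascii")).hexdigest()
    return ProteinSequence(id=pid, residues=residues, md5=md5,
                           length=len(residues))


def _scan_strand(residues: str, parent_id: str, parent_len: int, strand: str,
                 min_protein_length: int) -> List[OpenReadingFrame]:
    """Scan the three frames of one strand.

    ``residues`` is the forward sequence for '+' and its reverse
    complement for '-'; local coordinates are mapped back to the
    forward strand for '-'.
    """
    orfs = []
    n = len(residues)
    for offset in range(3):
        run_start = None  # local 0-based nt index of the run's first codon
        peptide: list[str] = []
        pos = offset
        while pos + 3 <= n:
            codon = residues[pos:pos + 3]
            if codon in _STOPS:
                if peptide:
                    orfs.extend(_emit(parent_id, parent_len, strand,
                                      run_start, pos + 3, "".join(peptide),
                                      True, min_protein_length))
                run_start, peptide = None, []
            else:
                if run_start is None:
                    run_start = pos
                peptide.append(_translate_codon(codon))
            pos += 3
        if peptide:  # run truncated by sequence end: no stop codon
            orfs.extend(_emit(parent_id, parent_len, strand,
                              run_start, pos, "".join(peptide),
                              False, min_protein_length))
    return orfs


def _emit(parent_id, parent_len, strand, local_start, local_end, peptide,
          has_stop, min_len):
    if len(peptide) < min_len:
        return []
    if strand == "+":
        nt_start = local_start + 1
        nt_end = local_end
    else:
        # local coords are on the reverse complement; reflect them
        nt_start = parent_len - local_end + 1
        nt_end = parent_len - local_start
    prot = _protein_for(parent_id, strand, nt_start, nt_end, peptide)
    return [OpenReadingFrame(parent_id=parent_id, strand=strand,
                             nt_start=nt_start, nt_end=nt_end,
                             protein=prot, has_stop=has_stop)]


def find_orfs(seq: NucleotideSequence,
              min_protein_length: int = DEFAULT_MIN_PROTEIN_LENGTH
              ) -> List[OpenReadingFrame]:
    """Find ORFs in all six reading frames of *seq*.

    Returns ORFs with translated length ≥ *min_protein_length*, sorted
    by (nt_start, nt_end, strand).  Zero ORFs is a valid result.
    """
    if min_protein_length < 1:
        raise ValueError("min_protein_length must be >= 1")
    fwd = seq.residues
    rev = str(Seq(fwd).reverse_complement())
    orfs = _scan_strand(fwd, seq.id, seq.length, "+", min_protein_length)
    orfs += _scan_strand(rev, seq.id, seq.length, "-", min_protein_length)
    orfs.sort(key=lambda o: (o.nt_start, o.nt_end, o.strand))
    return orfs


def map_to_nucleotide(orf: OpenReadingFrame, start: int, stop: int
                      ) -> Tuple[int, int, str]:
    """Project a protein residue interval onto the parent nucleotide.

    *start*..*stop* are 1-based inclusive residue coordinates within
    ``orf.protein``; the returned (nt_start, nt_end, strand) is 1-based
    inclusive on the forward strand with nt_start ≤ nt_end, and the
    span is always 3× the residue count.
    """
    if not (1 <= start <= stop <= orf.protein.length):
        raise ValueError(
            f"residue interval {start}..{stop} outside protein of length "
            f"{orf.protein.length}")
    if orf.strand == "+":
        nt_start = orf.nt_start + 3 * (start - 1)
        nt_end = orf.nt_start + 3 * stop - 1
    else:
        nt_end = orf.nt_end - 3 * (start - 1)
        nt_start = orf.nt_end - 3 * stop + 1
    return nt_start, nt_end, orf.strand
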