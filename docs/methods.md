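# Methods

This note documents the models and procedures sigscan implements, the
conventions it fixes where the field has no single standard, and what
its synthetic fixtures do and do not demonstrate.

## Sequence canonicalization and checksums

Protein input is whitespace-stripped, uppercased, and stripped of
trailing stop characters (`*`); an internal `*` or any character
outside the 20 standard residues plus B, Z, X, U, O is rejected with
the character and its 1-based position. The content address is the
lowercase MD5 hex digest of the canonical residue string — the de
facto convention for sequence cross-referencing, cheap to verify with
any independent MD5 implementation. The checksum is a pure function of
the canonical residues: identifiers and input case never affect it,
which is what makes deduplication and the match cache sound.
Ambiguity codes are passed through; analyzers decide their own
handling (the bundled profile scanner scores unknown residues 0).

## ORF finding and coordinate mapping

Nucleotide sequences (alphabet A, C, G, T, N) are scanned in all six
reading frames for maximal stop-free codon runs (stop-to-stop, not
ATG-anchored — the getorf-style convention that maximizes analyzer
coverage). Default minimum translated length: 50 residues,
configurable (`min_orf_length`). The terminating stop codon is
included in the nucleotide span when present but excluded from the
protein, so spans look like CDS features to GFF3 consumers; a run
truncated by the sequence end has no stop and its span is exactly
3×length. Translation uses the standard genetic code only; codons
containing N translate to X.

Protein-coordinate features map back through the ORF: for a `+` ORF,
residues *s..e* occupy bases `nt_start + 3(s−1)` to `nt_start + 3e −
1`; for a `−` ORF the first residue anchors at `nt_end` (the
high-coordinate end of the forward strand) and the interval reflects
accordingly. All coordinates everywhere are 1-based inclusive on the
forward strand; every mapped span has length 3× the residue count, and
translating the mapped bases (reverse-complemented for `−`) reproduces
the residue interval exactly — both properties are tested on random
sequences, with a strand-flip oracle (results on the reverse
complement equal strand-flipped, coordinate-reflected results).

## Analyzer models

**Patterns** are PROSITE-style: residue literals, `x` wildcard,
`[sets]`, `{negated sets}`, fixed `(n)` and ranged `(n,m)` repeats,
terminal anchors `<` and `>`; no nested groups. Repeat semantics are
resolved as: *report every distinct start position with its shortest
non-empty accepting window*. The scanner is a small dynamic program
over (element index → set of reachable offsets), which makes
minimality exact rather than an artifact of backtracking order; the
test suite checks it against an independent brute-force oracle that
expands every repeat-count combination and tests windows with the
`re` module. Patterns carry no score.

**Profiles** are L×20 position-weight matrices with a threshold;
every length-L window whose summed score reaches the threshold is a
raw hit, scored by the sum. Unknown residues score 0. Non-maximal
overlapping windows are retained at the raw stage: filtering is the
post-processor's job. Raising the threshold can only remove windows
(tested as a monotonicity property).

**Post-processing.** Two modalities, as real scan applications have:
`single_pass` marks all raw output filtered-in; `scan_filter` applies
clan-overlap resolution. Within a clan, candidate locations are ranked
by (score descending, start ascending, accession ascending) — a
scoreless location ranks below any scored one — and claimed greedily:
a location overlapping (≥1 shared residue) an already-kept location
loses. A multi-location match competes location-wise and survives if
any location survives; clanless matches always survive. Nothing is
deleted, only re-statused, so the operation conserves match count and
is idempotent. This rule is an explicit stand-in for member-specific
post-processing, not a reconstruction of any particular database's
algorithm.

## Job engine

Planning expands each job over the deduplicated checksum list:
chunkable steps get ⌈n/chunk_size⌉ instances (all chunks but the last
exactly chunk_size), non-chunkable steps one. Instance dependencies
follow step dependencies — chunk-aligned between chunkable steps,
fan-in onto non-chunkable, fan-out from non-chunkable. Cycles are
rejected at planning time with the offending step names.

Serial mode executes in deterministic topological order, ties broken
by (job, step, chunk index). Multiprocess mode dispatches descriptors
(self-contained: names, chunk checksums, working directory — artifacts
pass by path on the shared filesystem, not by message payload) onto a
FIFO queue polled by worker processes. Delivery is at-least-once:
every step writes to an instance-scoped temporary path and atomically
renames, so duplicate or re-executed instances leave identical bytes.
All step outputs and the final merge are canonically sorted, which is
what makes multiprocess output byte-identical to serial.

Worker management: the master spawns direct workers up to
`max_direct_workers` (default 4); surplus demand is delegated to an
existing worker, which spawns the next tier itself (recursively,
bounded by `max_tiers`, default 3). Workers expire after
`worker_lifetime` idle seconds (default 5). Failures: a step exception
or a worker death re-queues the instance until `retry_limit` attempts
(default 2), then the run aborts with the captured diagnostics; a
failed spawn is logged and tolerated, and with no workers at all the
master executes queued work inline so the run still completes. A
stall backstop re-queues outstanding instances after 10 s of silence
(covers the rare loss of an in-flight status message when a worker
dies). The queue is an in-process abstraction with two backends
(in-memory; OS-process queues); a message broker could be slotted in
behind the same contract. Cluster-scheduler submission is reduced to
the spawn hook; no scheduler-specific code ships.

Defaults with no field standard, chosen once for desk scale:
chunk_size 1000, backlog threshold 1 (spawn as soon as work queues).

## Annotation and the pathway rule

Annotation is a pure lookup: each filtered-in match gets its entry (or
none — unintegrated signatures are reported with empty annotation),
the entry's GO terms, and its pathway cross-references. EC numbers are
carried as ordinary cross-references with database `EC`; there is no
EC-specific logic, and no GO graph traversal.

A pathway is associated with an entry iff the fraction of *distinct*
matched proteins annotated with it in the reference annotation table
strictly exceeds 0.80 (81/100 associates; 80/100 does not; an empty
matched set associates nothing). The rule normally runs at
bundle-build time against the reference table, producing the entry's
stored cross-references; the same computation is exposed at run time.
The denominator is all distinct matched proteins present in the
reference table — the natural reading when no filtered subset is
defined.

## Match lookup store

A single-file SQLite database maps checksum → per-analysis match
lists, stamped with the exact {library: release version} mapping it
was computed under. A protein is a hit only if the stamp equals the
configured versions *and* the record covers every requested analysis;
hits are filtered to the requested analyses. Any mismatch, corruption
or unreachability degrades to all-misses with a warning — the cache is
an optimization, never a correctness dependency. The central
guarantee, tested end-to-end: a run served entirely from a store built
from a previous run's XML is byte-identical to recomputation (with a
fixed run date). Partial per-library reuse is out of scope. A
minimal HTTP front-end (POST a JSON list of checksums) preserves the
service deployment shape.

## Output formats

The in-memory result document is canonical; XML is its lossless
serialization (round-trip equality is tested on random documents), and
TSV, GFF3 and JSON are projections, so converting stored XML is
byte-identical to writing the target directly. The TSV has 15 columns
(id, checksum, length, analysis, signature accession/description,
start, stop, score, status, date, entry accession/description,
pipe-joined GO terms, pipe-joined pathways), `-` for missing values,
rows sorted by (id, analysis, signature, start), scores at three
decimals. GFF3 emits `protein_match` features on protein identifiers
and, for nucleotide runs, one `ORF` feature per translated ORF plus
match features projected onto the parent sequence with the ORF's
strand; analyzed protein sequences follow `##FASTA`. The run date is
an explicit document field (`--date`) so byte-equality is testable;
only filtered-in matches ever reach output. HTML/SVG rendering and
legacy dialects are out of scope; `--convert` rejects them with a
clear message.

## Synthetic fixtures

The generator emits, from a single seeded PRNG stream, random-uniform
background proteins with planted motif occurrences, the toy library
(`TOYLIB` 1.0: two clan-mates — a pattern and a profile — plus a
clanless pattern and a deliberately unintegrated signature), and an
integration bundle whose entry→pathway table is the output of the
>80% rule applied to engineered annotation fractions. Candidate
proteins are rejection-sampled until scanning finds *exactly* the
planted occurrences, so recall and precision against the recorded
ground truth are exact by construction. Nucleotide fixtures
reverse-translate each protein with random synonymous codons, flank
the CDS with in-frame stops, and embed it on a chosen strand/frame in
random background; expected ORF spans and projected match coordinates
are computed arithmetically from the embedding, independently of the
coordinate mapper under test. Default study conditions: 50 proteins
of 80–140 residues with 10 placements; engine-level checks use 6–12
proteins with small chunks so multiprocess runs exercise many
instances cheaply.

What passing on fixtures does **not** show: background composition is
uniform, not biological; the toy models have none of the statistical
calibration (E-values, HMM scoring) of real signature libraries; and
wall-clock scaling claims are out of scope. The fixtures validate the
*framework* — scheduling, caching, integration, formats, coordinate
arithmetic — not predictive power.

## Known limitations

- Single-host execution only; the queue contract would admit a real
  broker but none ships.
- No partial reuse of a lookup store across library-release changes.
- PROSITE repeat syntax is limited to fixed and (min,max) counts; no
  nested groups.
- Standard genetic code only; no gene prediction, splicing, or partial
  codons.
- Grandchild workers are monitored by their parent; if a parent and
  child die simultaneously the stall backstop, not death detection,
  recovers the work.
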