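# sigscan

A desk-scale protein function classification framework built around
protein *signature scanning*: sequences are searched against libraries
of predictive models (signatures — here PROSITE-style patterns and
position-weight profiles), raw hits are post-processed, and surviving
matches are integrated with curated entries carrying Gene Ontology
terms and pathway cross-references.

It is aimed at people who want the **architecture** of a large
signature-scanning pipeline — dependency-scheduled jobs, chunked
sequence sets, tiered master/worker execution, checksum-keyed result
caching, and a canonical multi-format output family — in a
self-contained package with no external scan binaries, licensed models
or services. The bundled analyzers are deliberately simple models
behind the same contract a real scan application would implement.

## What it does

- **Sequence model.** Input proteins are validated, uppercased and
  content-addressed by the MD5 of their canonical residue string;
  identical sequences are analyzed once and results fan back out to
  every submitted identifier. Nucleotide input is translated in all
  six reading frames (stop-to-stop ORFs) and features found on the
  translated proteins are projected back to nucleotide coordinates.
- **Analyzers.** Two modalities behind one contract: single-pass
  predictors whose raw output is final, and scan + post-process
  pipelines. Post-processing resolves overlapping hits within a
  *clan* (a group of related signatures): among locations overlapping
  by ≥1 residue only the best survives — highest score, then smaller
  start, then lexicographically smaller accession. The pattern
  scanner reports, for each distinct start, the shortest accepting
  window; the profile scanner reports every length-L window whose
  summed score reaches the threshold.
- **Job engine.** Each analysis is a declaratively wired job of steps
  (write chunk FASTA → scan → post-process → persist, with merging and
  branching allowed). Planning binds chunkable steps to
  ⌈n/chunk_size⌉ chunks of the deduplicated set. A master dispatches
  ready step instances onto a FIFO queue; workers poll, execute and
  report. When demand exceeds the direct-worker limit, workers spawn
  a further tier of workers. Step outputs are written atomically, so
  at-least-once delivery and worker death are harmless; serial and
  multiprocess modes produce byte-identical output.
- **Annotation.** Filtered matches are joined to entries, GO terms and
  pathway cross-references. A pathway is associated with an entry when
  strictly more than 80% of the distinct proteins matched by that entry
  are annotated with it in a reference annotation table.
- **Match lookup.** An embedded store keyed by sequence checksum and
  stamped with the exact library release versions short-circuits
  recomputation; a stamp mismatch or unreachable store degrades to
  recomputing everything. A minimal HTTP front-end serves batch
  checksum queries.
- **Output.** TSV (15 columns), a lossless canonical XML, GFF3 (with
  nucleotide-projected features and an appended `##FASTA` section) and
  JSON. `--convert` regenerates any format from stored XML,
  byte-identical to writing it directly.

## Worked example

Generate a synthetic fixture (50 random proteins with 10 planted motif
occurrences, a toy signature library, and an integration bundle), scan
it, and read the results:

```
$ sigscan fixtures --seed 1 --out fix --n-proteins 50 --n-placements 10
wrote fix/proteins.fasta
      fix/data
      fix/ground_truth.tsv

$ sigscan -i fix/proteins.fasta --data-dir fix/data -b out/run --date 2026-09-22
analyzed 50 distinct proteins; 10 matches; lookup hits 0, misses 50
wrote out/run.gff3
wrote out/run.json
wrote out/run.tsv
wrote out/run.xml
```

The first TSV row (tab-separated):

```
prot_0000  e7b21c91ffd9d2e252153bbe135c3e60  88  TOYLIB  TOY00001  zinc-knuckle-like pattern  5  9  -  filtered_in  2026-09-22  ENT00001  Toy zinc finger family  GO:0003677|GO:0008270  KEGG:K00001
```

reading: protein `prot_0000` (MD5 checksum, 88 residues) matched
signature `TOY00001` of library `TOYLIB` at residues 5–9 (patterns
carry no score, hence `-`); the match survived post-processing
(`filtered_in`), belongs to entry `ENT00001` ("Toy zinc finger
family") with two GO terms, and that entry is associated with pathway
`KEGG:K00001` (more than 80% of its matched reference proteins carry
that annotation). The fixture's `ground_truth.tsv` lists exactly the
planted occurrences; the run reports exactly those 10 matches.

Useful flags: `-t n` for nucleotide input (ORF translation + GFF3
back-projection), `--mode multiprocess` for parallel execution,
`--lookup out.db` / `--disable-precalc` for the match cache,
`-appl TOYLIB` to select analyses, `--convert run.xml -f TSV -o x.tsv`
for format conversion, `--config file.yaml` to override the bundled
defaults.

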