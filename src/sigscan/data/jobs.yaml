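# Declarative step wiring for an analysis job.  Each configured
# signature library becomes one job instantiated from this template;
# dependencies may merge (fan-in) and branch (fan-out).
analysis:
  steps:
    - name: write_fasta
      kind: write_fasta
      chunkable: true
      depends_on: []
    - name: scan
      kind: run_analyzer_scan
      chunkable: true
      depends_on: [write_fasta]
    - name: postprocess
      kind: run_postprocess
      chunkable: true
      depends_on: [scan]
    - name: persist
      kind: persist_matches
      chunkable: false
      depends_on: [postprocess]
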