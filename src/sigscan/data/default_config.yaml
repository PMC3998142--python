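# Built-in defaults for sigscan runs.  Every key may be overridden in a
# user config file (--config) or on the command line.
seq_type: p
formats: [tsv, xml, gff3, json]
analyses: null          # null = all analyses configured in data_dir
chunk_size: 1000
mode: serial            # serial | multiprocess
max_workers: 4
max_direct_workers: 4
max_tiers: 3
worker_lifetime: 5.0    # idle seconds before a worker expires
retry_limit: 2          # attempts per step instance
disable_precalc: false
lookup: null            # path to a match store, or an http URL
min_orf_length: 50      # minimum translated ORF length (residues)
date: null              # fixed run date for byte-reproducible output
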