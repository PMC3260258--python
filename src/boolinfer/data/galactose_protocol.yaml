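# Consensus protocol for the galactose test set: the full 24-variety panel,
# full stringency, edges kept when present in at least 4 of the 24 solutions.
name: galactose_protocol
genes: galactose_genes.txt
panel:
  include_log_ratio: true
stringency: 100
filter:
  min_count: 4
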