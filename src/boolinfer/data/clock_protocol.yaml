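# Consensus protocol for the circadian-clock test sets: 23 binarisation
# varieties (no sign-of-log2-ratio), full stringency, edges kept only when
# strictly more than 20% of the solutions agree (5 of 23).
name: clock_protocol
genes: clock_genes.txt
constraints: clock_constraints.txt
panel:
  include_log_ratio: false
stringency: 100
filter:
  min_fraction: 0.2
  strict: true
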