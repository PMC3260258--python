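# 14-gene Arabidopsis circadian-clock test set: 7 clock genes plus 7 genes
# from the glycolysis and flowering pathways.
CCA1
LHY
TOC1
GI
PRR5
PRR7
ELF4
CO
FT
SOC1
TPI
PGM
PGK
PGI1
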