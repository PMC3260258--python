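# Prior-knowledge constraints for the Arabidopsis circadian-clock test set.
# Conceptual: enzymatic genes barred from being regulators (parental nodes).
# Specific: no feedback from the flowering pathway to the core clock genes.
[conceptual]
PGI1
TPI
PGK
PGM
[specific]
CO	CCA1
CO	ELF4
CO	GI
CO	LHY
CO	PRR5
CO	PRR7
CO	TOC1
FT	CCA1
FT	ELF4
FT	GI
FT	LHY
FT	PRR5
FT	PRR7
FT	TOC1
SOC1	CCA1
SOC1	ELF4
SOC1	GI
SOC1	LHY
SOC1	PRR5
SOC1	PRR7
SOC1	TOC1
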