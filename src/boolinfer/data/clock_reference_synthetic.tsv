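# SYNTHETIC curator stand-in for a signed Arabidopsis circadian-clock
# reference network; transcribed/simplified from the general clock and
# flowering-time literature, editable by the user.  Not a published gold
# standard.
CCA1	TOC1	-
CCA1	ELF4	-
LHY	TOC1	-
LHY	ELF4	-
TOC1	CCA1	+
TOC1	LHY	+
TOC1	GI	-
GI	TOC1	+
PRR7	CCA1	-
PRR7	LHY	-
PRR5	CCA1	-
PRR5	LHY	-
GI	CO	+
CO	FT	+
FT	SOC1	+
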