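# SYNTHETIC curator stand-in for a signed galactose-pathway reference
# network (S. cerevisiae); transcribed/simplified from textbook GAL-pathway
# regulation, editable by the user.  Not a published gold standard.
GAL4	GAL1	+
GAL4	GAL2	+
GAL4	GAL7	+
GAL4	GAL10	+
GAL4	GAL3	+
GAL4	GAL80	+
GAL4	PGM2	+
GAL80	GAL1	-
GAL80	GAL2	-
GAL80	GAL7	-
GAL80	GAL10	-
GAL3	GAL80	-
MIG1	GAL1	-
MIG1	GAL4	-
MIG1	GAL3	-
SNF1	MIG1	-
SSN6	GAL1	-
TUP1	GAL1	-
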