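# 20-gene galactose-utilisation test set (S. cerevisiae diauxic shift):
# 17 pathway-relevant genes plus 3 irrelevant cell-cycle transcription factors.
GAL1
GAL2
GAL3
GAL4
GAL7
GAL10
GAL11
GAL80
PGM1
PGM2
LAP3
EGD1
EGD2
MIG1
SSN6
TUP1
SNF1
TFB1
TFB2
TFB3
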