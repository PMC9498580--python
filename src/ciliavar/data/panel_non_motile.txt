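# Non-motile (primary) cilia genes.  Reconstructed from the variant-bearing
# genes of the study tables; the full published panel is larger.
PIBF1
IQCE
TTLL6
CFAP100
CFAP77
INPP5E
OFD1
AK7
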