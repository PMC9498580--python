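# Ciliogenesis and ciliary trafficking genes.  Reconstructed from the
# variant-bearing genes of the study tables; the full published panel is larger.
SAXO2
PIBF1
UBXN10
TTLL6
TRPV4
IFT46
MORN3
TRAF3IP1
OFD1
MORN1
ARMC9
NEK11
AGBL2
BBS7
SPATA4
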