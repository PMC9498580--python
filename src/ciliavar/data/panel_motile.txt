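# Motile cilia genes (outer/inner dynein arms, central apparatus, radial
# spokes, nexin-dynein regulatory complex).  Reconstructed from the
# variant-bearing genes of the study tables; the full published panel is larger.
DRC7
TTC25
RSPH14
NEK5
LRGUK
CFAP43
DNAH11
DNAH10
DNAH3
HYDIN
DNAH9
WDR63
CCDC113
OFD1
CFAP70
ARMC9
CEP295
SPAG17
DNAI1
MNS1
TEKT2
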