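# SYNTHETIC interaction network (STRING protein-links dialect, combined
# scores 0-999).  The real STRING v11.5 network is an external database and
# is not redistributed; this hand-built stand-in encodes the pairwise
# interactions the study reports between deleterious-variant genes
# (DNAH9-HYDIN, CFAP43-WDR63, TRAF3IP1-IFT46, OFD1-PIBF1, the DNAH9/DNAH3/
# WDR63/CFAP70 complex, DNAH11-OFD1 weak, DNAI1-SPAG17) plus plausible
# background edges within the dynein/axoneme and primary-cilium modules.
# Scores follow the confidence tiers 150/400/700/900.
protein1	protein2	combined_score
DNAH9	HYDIN	900
DNAH9	DNAH11	900
DNAH9	DNAI1	900
DNAH11	DNAI1	900
DNAH9	DNAH3	900
DNAH9	WDR63	700
DNAH3	WDR63	700
CFAP70	DNAH9	400
CFAP70	DNAH3	400
CFAP43	WDR63	700
CFAP43	CFAP70	700
CFAP43	CFAP100	400
DNAH9	TTC25	700
DNAI1	TTC25	700
DNAH11	HYDIN	400
SPAG17	HYDIN	700
DNAI1	SPAG17	700
DNAH10	DNAH9	700
DNAH10	DNAH11	700
DNAH3	DNAI1	400
WDR63	DNAI1	400
MNS1	DNAH9	400
TEKT2	SPAG17	400
RSPH14	SPAG17	400
DRC7	CCDC113	400
CCDC113	TTC25	400
DNAH11	OFD1	150
OFD1	PIBF1	700
BBS7	OFD1	700
BBS7	PIBF1	400
TRAF3IP1	OFD1	400
TRAF3IP1	IFT46	700
IFT46	BBS7	400
INPP5E	OFD1	700
INPP5E	BBS7	700
INPP5E	IQCE	400
ARMC9	TTLL6	400
ARMC9	OFD1	400
CEP295	OFD1	400
NEK11	NEK5	400
MORN3	MORN1	150
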