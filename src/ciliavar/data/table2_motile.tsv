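patient_id	gene	dbsnp	nt_change	consequence	aa_change	sift_label	sift_score	pp2_humdiv_label	pp2_humdiv_score	pp2_humvar_label	pp2_humvar_score	ma_label	ma_score	cadd_phred	loftool_label	loftool_score	allele_freq	zygosity	chromosome_class	inheritance	panel	clinical_class	reported_deleterious	variant_associated
T180101	DRC7	rs199828087	c.1819C>T	missense	p.R607C	D	0.04	D	0.91	PD	0.99	L	1.81				2.83 × 10^-5	HE	autosomal	NR	motile	VUS	Yes	No
T180101	TTC25	rs782333806	c.218C>T	missense	p.S73L	D	0	PD	1	PD	0.97	M	2.54				5.94 × 10^-4	HE	autosomal	AR	motile	VUS	Yes	No
T180101	RSPH14	rs780971104	c.488A>G	missense	p.E163G	D	0	B	0.02	B	0.02	M	2.71				4.63 × 10^-4	HE	autosomal	NR	motile	VUS	Yes	No
T180201	NEK5	rs35465612	c.1420C>T	missense	p.R474C	D	0	PD	1	PD	0.95	M	2.44				9.27 × 10^-3	HE	autosomal	NR	motile	VUS	Yes	No
T180201	LRGUK	rs140175129	c.2044C>T	missense	p.R682C	D	0	PD	0.96	B	0.27	N	0				3.44 × 10^-2	HE	autosomal	NR	motile	VUS	Yes	No
T180201	CFAP43	rs150378110	c.3935G>A	missense	p.R1312H	T	0.12	PD	0.99	PD	0.85	M	2.59				1.21 × 10^-3	HE	autosomal	AD	motile	VUS	Yes	No
T180201	DNAH11	rs1243678738	c.12577C>T	nonsense	p.Q4193*									48			2.897 × 10^-5	HE	autosomal	AR	motile	VUS	Yes	No
T180301	DNAH10	rs779897384	c.1468C>A	missense	p.P490T	D	0.01	PD	0.99	PD	0.97	M	3.04				1.98 × 10^-3	HE	autosomal	NR	motile	VUS	Yes	No
T180301	DNAH3	rs182462514	c.608T>C	missense	p.M203T	T	0.1	PD	0.45	B	0.07	M	2.17				3.95 × 10^-3	HE	autosomal	NR	motile	VUS	Yes	No
T180401	HYDIN	New	c.3332C>T	missense	p.P1111L	D	0	PD	0.99	PD	0.98	M	2.76				New	HO	autosomal	AR	motile	VUS	Yes	No
T180401	DNAH9	rs139596704	c.3050A>G	missense	p.Y1017C	D	0	PD	0.98	PD	0.82	M	2.93				5.30 × 10^-2	HE	autosomal	AR	motile	VUS	Yes	No
T180401	DNAH9	rs777167537	c.5151+1G>A	splice										34			1.1 × 10^-4	HE	autosomal	AR	motile	VUS	Yes	No
T180701	WDR63	rs1056616254	c.1742C>A	missense	p.T581N	D	0	PD	0.98	PD	0.64	M	2.58				1.19 × 10^-5 *	HE	autosomal	NR	motile	VUS	Yes	No
T180701	CFAP43	rs117768807	c.589G>A	missense	p.V197M	D	0	PD	0.99	PD	0.97	L	1.76				3.05 × 10^-4	HE	autosomal	AD	motile	VUS	Yes	No
T180701	CCDC113	rs144246110	c.300A>T	missense	p.K100N	D	0	PD	1.0	PD	0.99	M	2.85				2.03 × 10^-3	HE	autosomal	NR	motile	VUS	Yes	No
T180801	DNAH10	rs755673190	c.8228C>T	missense	p.P2743L	D	0.05	B	0.005	B	0.005	M	2.53				2.83 × 10^-5	HE	autosomal	NR	motile	VUS	Yes	No
T180801	OFD1	rs779051357	c.2482T>G	missense	p.F828V	T	0.07	PD	0.90	PD	0.59	M	2.43				5.17 × 10^-5	HEMY	X	XLD	motile	VUS	Yes	No
T180901	WDR63	rs138379333	c.922G>A	missense	p.A308T	D	0.04	PD	0.79	B	0.14	M	2.49				5.39 × 10^-2	HE	autosomal	NR	motile	VUS	Yes	No
T180901	CFAP70	rs575812060	c.3079T>A	missense	p.C1027S	D	0.02	PD	0.98	PD	0.90	M	2.43				2.60 × 10^-3	HE	autosomal	AR	motile	VUS	Yes	No
T180901	DNAH3	rs141197402	c.8597A>G	missense	p.H2866R	D	0	PD	0.83	PD	0.49	L	1.29				1.87 × 10^-3	HE	autosomal	NR	motile	VUS	Yes	No
T180901	DNAH9	rs267604735	c.7150G>A	missense	p.G2384R	D	0.04	PD	0.99	D	0.91	H	3.71				5.79 × 10^-5	HE	autosomal	AR	motile	VUS	Yes	No
T180901	ARMC9	rs386656198	c.878C>T	missense	p.T293M	T	1	PD	1.0	D	0.98	M	2.33				5.24 × 10^-4	HE	autosomal	AR	motile	VUS	Yes	No
T181001	DNAH11	rs199789835	c.8521A>G	missense	p.S2841G	D	0.02	PD	0.95	PD	0.79	M	2.95				2.23 × 10^-4	HE	autosomal	AR	motile	VUS	Yes	No
T181001	OFD1	New	c.2610G>C	missense	p.Q870H	D	0.04	PD	0.89	PD	0.63	M	2.12				New	HEMY	X	XL	motile	VUS	Yes	No
T181001	CEP295	rs763108226	c.512C>T	missense	p.P171L	D	0.04	PD	0.72	B	0.25						5.37 × 10^-3	HE	autosomal	ND	motile	VUS	Yes	No
T181101	SPAG17	rs140959339	c.430C>T	missense	p.R144W	D	0	PD	1.0	PD	0.99	M	2.70				2.37 × 10^-2	HE	autosomal	NR	motile	VUS	Yes	No
T181101	DNAI1	rs771320807	c.203G>A	missense	p.R68Q	D	0	PD	0.99	PD	0.91	M	2.45				2.89 × 10^-4	HE	autosomal	AR	motile	VUS	Yes	No
T181101	MNS1	rs549395315	c.605delA	frameshift	p.L202SfsTer									29.2			NF	HE	autosomal	AR	motile	VUS	Yes	No
T181201	SPAG17	rs1028261558	c.1700C>A	missense	p.P567Q	D	0.01	PD	0.97	PD	0.84	M	2.62				1.74 × 10^-4	HE	autosomal	NR	motile	VUS	Yes	No
T181201	DNAH9	rs139596704	c.3050A>G	missense	p.Y1017C	D	0	PD	0.98	PD	0.82	M	2.93				5.30 × 10^-2	HE	autosomal	AR	motile	VUS	Yes	No
T181401	TEKT2	rs144497984	c.1114C>T	missense	p.R372W	D	0.01	PD	1.0	PD	0.99	M	2.86				2.21 × 10^-2	HE	autosomal	NR	motile	VUS	Yes	No
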