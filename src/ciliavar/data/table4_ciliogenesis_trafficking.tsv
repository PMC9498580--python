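patient_id	gene	dbsnp	nt_change	consequence	aa_change	sift_label	sift_score	pp2_humdiv_label	pp2_humdiv_score	pp2_humvar_label	pp2_humvar_score	ma_label	ma_score	cadd_phred	loftool_label	loftool_score	allele_freq	zygosity	chromosome_class	inheritance	panel	clinical_class	reported_deleterious	variant_associated
T180101	SAXO2	rs116324279	c.1111T>C	missense	p.S371P	T	0.04	PD	0.87	PD	0.63	M	2.14				5.65 × 10^-4	HE	autosomal	ND	ciliogenesis_trafficking	VUS	Yes	No
T180201	PIBF1	rs17089782	c.1214G>A	missense	p.R405Q	D	0	PD	1	PD	0.99	M	2.56				0.1021	HE	autosomal	AR	ciliogenesis_trafficking	likely_pathogenic	Yes	Jb
T180201	UBXN10	rs11556959	c.794A>G	missense	p.H265R	D	0.01	PD	0.98	PD	0.82	M	2.32				2.60 × 10^-4	HE	autosomal	NR	ciliogenesis_trafficking	VUS	Yes	No
T180301	TTLL6	rs184362955	c.517C>T	missense	p.R173W	D	0	PD	1.0	PD	1.0	H	4.64				8.89 × 10^-3	HE	autosomal	NR	ciliogenesis_trafficking	VUS	Yes	No
T180701	TRPV4	rs187864727	c.649G>T	missense	p.A217S	T	0.13	PD	1.0	PD	0.99	M	2.00				6.85 × 10^-2	HE	autosomal	AD	ciliogenesis_trafficking	VUS	Yes	NEDY
T180701	IFT46	rs145438119	c.454C>G	missense	p.P152A	D	0.01	PD	1.0	PD	1.0	M	3.25				3.16 × 10^-3	HE	autosomal	AR	ciliogenesis_trafficking	VUS	Yes	No
T180701	MORN3	rs782293129	c.616G>C	missense	p.A206P	D	0	PD	1.0	PD	1.0	M	2.87				2.03 × 10^-4	HE	autosomal	ND	ciliogenesis_trafficking	VUS	Yes	No
T180701	TRAF3IP1	rs761035757	c.838C>T	missense	p.R280W	D	0.01	PD	0.99	PD	0.91	L	1.79				2.56 × 10^-4	HE	autosomal	AR	ciliogenesis_trafficking	VUS	Yes	No
T180801	TRPV4	rs187864727	c.649G>T	missense	p.A217S	T	0.13	PD	1.0	PD	0.99	M	2.00				6.85 × 10^-2	HE	autosomal	AD	ciliogenesis_trafficking	VUS	Yes	NEDY
T180801	PIBF1	rs17089782	c.1214G>A	missense	p.R405Q	D	0	PD	1.0	PD	0.96	M	2.56				0.1021	HO	autosomal	AR	ciliogenesis_trafficking	likely_pathogenic	Yes	Jb
T180801	OFD1	rs779051357	c.2482T>G	missense	p.F828V	T	0.07	PD	0.90	PD	0.59	M	2.43				5.17 × 10^-5	HEMY	X	XLD	ciliogenesis_trafficking	VUS	Yes	No
T180901	MORN1	rs34587196	c.757C>T	missense	p.R253W	D	0	PD	1.0	PD	0.99	M	2.25				6.57 × 10^-3	HE	autosomal	NR	ciliogenesis_trafficking	VUS	Yes	No
T180901	ARMC9	rs386656198	c.878C>T	missense	p.T293M	T	1	PD	1.0	D	0.98	M	2.33				5.24 × 10^-4	HE	autosomal	AR	ciliogenesis_trafficking	VUS	Yes	No
T181001	NEK11	rs140058289	c.127G>C	missense	p.V43L	D	0.01	PD	0.93	PD	0.52	M	3.41				4.80 × 10^-2	HE	autosomal	NR	ciliogenesis_trafficking	VUS	Yes	No
T181001	OFD1	New	c.2610G>C	missense	p.Q870H	D	0.04	PD	0.89	PD	0.63	M	2.12				New	HEMY	X	XL	ciliogenesis_trafficking	VUS	Yes	No
T181201	AGBL2	rs7941404	c.956G>A	missense	p.R319H	T	0.09	PD	0.99	PD	0.91	M	2.49				9.9 × 10^-5 *	HE	autosomal	NR	ciliogenesis_trafficking	VUS	Yes	No
T181201	PIBF1	rs17089782	c.1214G>A	missense	p.R405Q	D	0	PD	1.0	PD	0.99	M	2.56				0.1021	HO	autosomal	AR	ciliogenesis_trafficking	likely_pathogenic	Yes	Jb
T181401	BBS7	rs199891330	c.508A>G	missense	p.R170G	D	0.02	PD	1.0	PD	0.99	M	2.66				9.84 × 10^-4	HE	autosomal	AR	ciliogenesis_trafficking	VUS	Yes	No
T181401	SPATA4	rs765034017	c.599A>C	missense	p.N200T	D	0.02	PD	0.98	PD	0.88	M	2.17				8.67 × 10^-5	HE	autosomal	ND	ciliogenesis_trafficking	VUS	Yes	No
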