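patient_id	gene	dbsnp	nt_change	consequence	aa_change	sift_label	sift_score	pp2_humdiv_label	pp2_humdiv_score	pp2_humvar_label	pp2_humvar_score	ma_label	ma_score	cadd_phred	loftool_label	loftool_score	allele_freq	zygosity	chromosome_class	inheritance	panel	clinical_class	reported_deleterious	variant_associated
T180101	PIBF1	rs17089782	c.1214G>A	missense	p.R405Q	D	0	PD	1	PD	0.99	M	2.56				0.1021	HE	autosomal	AR	non_motile	likely_pathogenic	Yes	Jb
T180201	IQCE	rs200648086	c.1688T>C	missense	p.L563S	D	0	B	0.19	B	0.20	M	2.31				5.23 × 10^-4	HE	autosomal	AR	non_motile	VUS	Yes	No
T180301	TTLL6	rs184362955	c.517C>T	missense	p.R173W	D	0	PD	1.0	PD	1.0	H	4.64				8.89 × 10^-3	HE	autosomal	NR	non_motile	VUS	Yes	No
T180401	CFAP100	rs149511023	c.589G>A	missense	p.A197T	T	0.04	PD	0.99	PD	0.85	M	2.71				6.85 × 10^-3	HE	autosomal	ND	non_motile	VUS	Yes	No
T180701	CFAP77	rs11243798	c.551G>A	missense	p.R184H	D	0.04	PD	1	PD	0.99	M	2.65				5.03 × 10^-3	HE	autosomal	ND	non_motile	VUS	Yes	No
T180701	CFAP100	rs754767651	c.1292G>C	missense	p.R430T	D	0	PD	0.99	PD	0.84	L	1.76				3.76 × 10^-4	HE	autosomal	ND	non_motile	VUS	Yes	No
T180801	PIBF1	rs17089782	c.1214G>A	missense	p.R405Q	D	0	PD	1.0	PD	0.96	M	2.56				0.1021	HO	autosomal	AR	non_motile	likely_pathogenic	Yes	Jb
T180801	IQCE	rs375144768	c.784C>T	missense	p.L262F	D	0	PD	1.0	PD	0.99	M	2.59				2.60 × 10^-4	HE	autosomal	AR	non_motile	VUS	Yes	No
T180801	INPP5E	rs138150684	c.1360G>A	missense	p.D454N	T	0.06	PD	1.0	PD	0.88	M	1.99				1.96 × 10^-4 *	HE	autosomal	AR	non_motile	VUS	Yes	No
T180801	OFD1	rs779051357	c.2482T>G	missense	p.F828V	T	0.07	PD	0.90	PD	0.59	M	2.43				5.17 × 10^-5	HEMY	X	XLD	non_motile	VUS	Yes	No
T181001	OFD1	New	c.2610G>C	missense	p.Q870H	D	0.04	PD	0.89	PD	0.63	M	2.12				New	HEMY	X	XL	non_motile	VUS	Yes	No
T181001	AK7	rs746369518	c.159_170del	frameshift	p.(Glu53_Glu56del)										PD	0.514	3 × 10^-3	HE	autosomal	AR	non_motile	VUS	Yes	No
T181201	PIBF1	rs17089782	c.1214G>A	missense	p.R405Q	D	0	PD	1.0	PD	0.99	M	2.56				0.1021	HO	autosomal	AR	non_motile	likely_pathogenic	Yes	Jb
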