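patient_id	gene	dbsnp	nt_change	consequence	aa_change	sift_label	sift_score	pp2_humdiv_label	pp2_humdiv_score	pp2_humvar_label	pp2_humvar_score	ma_label	ma_score	cadd_phred	loftool_label	loftool_score	allele_freq	zygosity	chromosome_class	inheritance	panel	clinical_class	reported_deleterious
T180101	KDM6A	rs780238270	c.232C>T	missense	p.R78C	T	0.15	B	0.05	B	0.009	L	1.31				3.95 × 10^-4 *	HEMY	X	XLD	tga_associated	unclassified	No
T180101	FOXH1	rs899189505	c.187G>A	missense	p.V63I	T	0.69	B	0.251	B	0.083	N	-1.435				5.81 × 10^-5	HE	autosomal	NR	tga_associated	unclassified	No
T180201	GDF1	rs944730356	c.404C>T	missense	p.A135V	T	0.54	B	0.015	B	0.008	N	0.6				0.001301	HE	autosomal	AD	tga_associated	unclassified	No
T180201	KMT2D	New	c.547C>T	missense	p.P183S	T	0.62	PD	0.959	PD	0.6	N	0.55				New	HE	autosomal	AD	tga_associated	unclassified	Yes
T180201	MEGF8	rs769862975	c.1315C>T	missense	p.R439W	D	0	PD	1	PD	0.948	M	2.27				6.13 × 10^-4	HE	autosomal	AR	tga_associated	unclassified	Yes
T180301	KMT2D	rs201628357	c.15686G>A	missense	p.R5229H	D	0.04	PD	1	PD	0.98	N	0.255				2.49 × 10^-5 *	HE	autosomal	AD	tga_associated	unclassified	Yes
T181001	MEGF8	rs1281253733	c.2344C>T	missense	p.R782W	D	0.085	PD	0.962	D	0.898	N	0.345				8.11 × 10^-6	HE	autosomal	AR	tga_associated	unclassified	Yes
T181101	DNAI1	rs771320807	c.203G>A	missense	p.R68Q	D	0.0	PD	0.998	PD	0.917	M	2.455				2.89 × 10^-5	HE	autosomal	AR	tga_associated	unclassified	Yes
T181101	DISC1	rs753171376	c.1852C>G	missense	p.P618A	T	0.08	PD	0.995	PD	0.865	M	2.24				2.83 × 10^-4 *	HE	autosomal	AR	tga_associated	unclassified	Yes
T181101	CCDC65	rs200575863	c.470+3A>G	splice										16.55			8.52 × 10^-4	HE	autosomal	AR	tga_associated	unclassified	No
T181201	SLC4A1	rs2285644	c.2561C>T	missense	p.P854L	D	0.04	PD	0.823	B	0.140	M	2.66				0.04128	HE	autosomal	NR	tga_associated	unclassified	Yes
T181201	CLASP1	rs373752835	c.170C>T	missense	p.S57F	T	0.08	PD	0.985	PD	0.55	M	2.08				2.89 × 10^-5	HE	autosomal	NR	tga_associated	unclassified	Yes
T181401	PLB1	rs745799206	c.2089-2A>G	splice										33			8.674 × 10^-5	HE	autosomal	NR	tga_associated	unclassified	Yes
T181401	CLASP1	New	c.1110T>G	missense	p.D370E	T	0.92	B	0	B	0.001	N	-0.175				New	HE	autosomal	NR	tga_associated	unclassified	No
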