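chrom	pos	ref	alt	gene	consequence	codons	aa_change	sift	mutation_taster	polyphen2	pmut	gerp
chr6	90418252	C	G	MDN1	missense	GAC7861CAC	p.D2621H	DAMAGING	polymorphism			2.23
chr14	21860964	C	T	CHD8	missense	CGT5636CAT	p.R1879H	DAMAGING	disease_causing			5.34
chr9	125582872	T	C	PDCL	missense	GAT398GGT	p.D133G	DAMAGING	disease_causing			5.47
chr17	55183450	G	A	AKAP1	missense	GTG625ATG	p.V209M	DAMAGING	polymorphism			4.22
chr15	39885853	G	A	THBS1	missense	GGA3251GAA	p.G1084E	DAMAGING	disease_causing			5.78
chr16	16170185	G	T	ABCC1	missense	GGG1915TGG	p.G639W	DAMAGING	disease_causing			4.11
chr1	1470881	G	A	TMEM240	missense	TCG380TTG	p.S127L	DAMAGING	disease_causing			3.37
chr7	73279329	C	A	WBSCR28	missense	CAG79AAG	p.Q27K	DAMAGING	polymorphism			4.43
chr9	2717768	C	G	KCNV2	missense	TCC29TGC	p.S10C	DAMAGING	disease_causing			4.45
chr7	99160120	A	C	ZNF655	missense							3.92
chr15	41275952	G	T	INO80	missense							2.69
chr10	116225553	G	A	ABLIM1	missense	CGG1345TGG	p.R449W	DAMAGING	disease_causing			3.37
chr1	26368197	T	C	SLC30A2	missense	ATG685GTG	p.M229V	DAMAGING	disease_causing			5.6
chr20	30232655	T	C	COX4I2	missense	GTG464GCG	p.V155A	DAMAGING	disease_causing			4.38
chr6	167570520	G	A	GPR31	missense	ACG800ATG	p.T267M	DAMAGING	polymorphism			2.65
chr6	168366533	G	A	MLLT4	missense	GGA4993AGA	p.G1665R	DAMAGING	disease_causing			5.03
chr16	20492206	C	T	ACSM2A	missense	ACG1472ATG	p.T491M	DAMAGING	polymorphism			3.26
chr20	420894	C	T	TBC1D20	missense	GTG766ATG	p.V256M	DAMAGING	disease_causing			5.65
chr9	110249480	G	T	KLF4	missense							3.45
chr3	196921405	A	G	DLG1	missense	ATC374ACC	p.I125T	TOLERATED	disease_causing			5.17
chr6	152536152	C	T	SYNE1	missense	CGT22022CAT	p.R7341H	TOLERATED	disease_causing			5.07
chr7	87051466	T	C	ABCB4	missense	ATT2287GTT	p.I763V	TOLERATED	polymorphism			4.85
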