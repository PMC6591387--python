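gene	chrom	pos	ref	alt	protein_change	consequence	ref_af	ref_ac	cadd_phred	ms_ac	ctrl_ac	ms_enriched_star
CASP1	11	104901069	A	-	p.Asn205fs	frameshift	4.10e-6	1		1	0	0
CASP8	2	202131331	C	A	p.Ala100Asp	missense		0	24.4	1	0	0
DHX58	17	40257124	G	C	p.Thr438Arg	missense	4.07e-6	1	26.7	1	0	0
EIF2AK2	2	37336412	T	A	p.Glu468Asp	missense		0	25.4	1	0	0
FOXO3	6	108985199	A	G	p.Asp388Gly	missense	4.06e-6	1	23.3	1	0	0
HDAC6	X	48681075	A	G	p.Thr795Ala	missense		0	25.5	0	1	0
HSP90AB1	6	44220815	T	G	p.Cys589Gly	missense	4.08e-6	1	22.3	1	0	0
IFIH1	2	163134114	T	C	p.Met619Val	missense	8.14e-6	2	24.4	2	0	1
MEFV	16	3304478	-	C	p.Gln198fs	frameshift		0		1	0	0
NLRP1	17	5445285	T	-	p.Asn864fs	frameshift		0		1	0	0
NLRP3	1	247588351	C	A	p.Leu536Met	missense		0	24	1	0	0
POLR3A	10	79741230	C	T	p.Asp1283Asn	missense	8.13e-6	2	35	1	0	0
POLR3A	10	79769710	C	T	p.Arg561Gln	missense	8.12e-6	2	35	1	0	0
POLR3A	10	79745740	G	A	p.Arg998Cys	missense	8.12e-6	2	25.1	1	0	0
POLR3A	10	79753041	T	G	p.Ile901Leu	missense		0	22.6	1	0	0
POLR3A	10	79770247	T	G	p.Ile542Leu	missense		0	25.2	1	0	0
POLR3A	10	79764601	T	C	p.Gln707Arg	missense	4.06e-6	1	22.6	1	0	0
POP1	8	99161077	C	T	p.Pro582Leu	missense		0	33	1	0	0
PTPN2	18	12794395	C	T	p.Arg377Gln	missense		0	27.2	1	0	0
PTPN22	1	114399219	G	A	p.Ala144Val	missense		0	22.1	1	0	0
PTPRC	1	198701436	C	T	p.Pro661Leu	missense	4.08e-6	1	34	1	0	0
PTPRC	1	198665899	C	A	p.His53Gln	missense		0	22.9	1	0	0
RIPK2	8	90782096	C	T	p.Pro194Ser	missense		0	32	2	0	1
SIRT2	19	39371539	T	C	c.748-2A>G	splice_site		0	20.6	1	0	0
SIRT2	19	39380575	G	A	p.Pro99Ser	missense	4.06e-6	1	25.7	1	0	0
TYK2	19	10468526	C	T	p.Ala794Thr	missense		0	23.1	1	1	0
TYK2	19	10479064	G	A	p.Ala75Val	missense	8.12e-6	2	25.3	1	0	0
TYK2	19	10468793	C	T	p.Gly733Ser	missense	4.21e-6	1	25	1	0	0
ULK1	12	132396530	C	T	p.Pro331Leu	missense	8.15e-6	2	25.7	0	1	0
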