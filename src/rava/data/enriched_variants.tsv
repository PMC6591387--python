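gene	chrom	pos	ref	alt	protein_change	consequence	ref_af	ref_ac	ref_ac_hom	cadd_phred	ms_ac	ms_ac_hom	ctrl_ac	ctrl_ac_hom
CARD18	11	105009760	C	A	p.Gly18Val	missense	1.63e-5	4	0	11.83	3	0	0	0
CHUK	10	101959733	G	A	p.Pro575Leu	missense	1.63e-5	4	0	24.4	2	0	0	0
DHX58	17	40257832	CTG	-	p.Gln391del	inframe_indel	4.11e-6	1	0		2	0	0	0
DUSP1	5	172197790	C	T	p.Ala56Thr	missense	0.022276	2192	36	22.7	12	0	6	0
HDAC6	X	48681187	G	A	p.Arg832His	missense	0.023789	4046	39	23.9	17	14	7	4
IFIH1	2	163134090	C	A	p.Glu627*	stop_gained	0.003199	786	1	38	7	0	1	0
IL4	5	132015548	G	A	p.Arg109Gln	missense	7.76e-5	19	0	14.77	2	0	0	0
LRRFIP1	2	238671578	T	C	p.Ser408Pro	missense	2.44e-5	6	0	2.929	2	0	0	0
CGAS	6	74161604	C	T	p.Gly101Arg	missense	0.015178	2080	25	8.00	61	0	15	0
NLRP1	17	5424908	C	T	p.Arg1240His	missense	4.47e-5	11	0	0.108	3	0	0	0
PTPRC	1	198718604	G	A	p.Asp1000Asn	missense	0.000193	47	0	28.5	3	0	1	0
SIRT2	19	39379770	C	T	p.Arg153His	missense	0.008683	2129	19	34	9	2	3	0
TBK1	12	64891037	G	C	p.Glu653Gln	missense	0.000254	56	0	18.96	2	0	0	0
TICAM1	19	4816670	G	C	p.Leu574Val	missense	0.000138	34	0	0.001	2	0	0	0
ZBP1	20	56195349	C	T	p.Met1?	start_lost	0.014182	3042	32	13.4	11	0	4	0
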