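gene	category
NLRP1	essential_inflammasome
NLRP3	essential_inflammasome
PYCARD	essential_inflammasome
CASP1	essential_inflammasome
EIF2AK2	priming
DDX58	priming
IFIH1	priming
DHX58	priming
TMEM173	priming
ZBP1	priming
POLR3A	priming
CGAS	priming
LRRFIP1	priming
MYD88	priming
TBK1	priming
IKBKE	priming
IRF3	priming
IRF7	priming
TYK2	priming
JAK1	priming
MAVS	priming
STAT1	priming
STAT2	priming
FLI1	priming
TICAM1	priming
CHUK	priming
HSP90AA1	priming
HSP90AB1	priming
HDAC6	sequestration
NR1H4	sequestration
CASP8	sequestration
FADD	sequestration
POP1	sequestration
PYDC2	sequestration
PYDC5	sequestration
CARD16	sequestration
CARD17	sequestration
CARD18	sequestration
BRCC3	ptm_autophagy
MARCH7	ptm_autophagy
FBXL2	ptm_autophagy
MEFV	ptm_autophagy
ULK1	ptm_autophagy
TRIM31	ptm_autophagy
MAPK8	ptm_autophagy
ATG5	ptm_autophagy
LRRFIP2	ptm_autophagy
BECN1	ptm_autophagy
ATG16L1	ptm_autophagy
MAP1LC3B	ptm_autophagy
NOD2	ptm_autophagy
RIPK2	ptm_autophagy
SQSTM1	ptm_autophagy
SESN2	ptm_autophagy
IL4	ptm_autophagy
DUSP1	ptm_autophagy
SIRT2	ptm_autophagy
FOXO3	ptm_autophagy
PTPN2	ptp
PTPN6	ptp
PTPN22	ptp
PTPRC	ptp
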