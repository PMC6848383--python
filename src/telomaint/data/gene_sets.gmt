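extension of telomeres	telomerase-mediated telomere extension	TERT	TERC	DKC1	NHP2	NOP10	GAR1	WRAP53	RUVBL1	RUVBL2	SHQ1	PARN	NAF1	ACD	POT1	TEP1	PIF1
telomere maintenance	shelterin and telomere length homeostasis	TERF1	TERF2	TERF2IP	TINF2	POT1	ACD	RTEL1	TNKS	TNKS2	STN1	TEN1	CTC1	TERT	TERC	DKC1	OBFC1
ALT genes	alternative lengthening of telomeres	ATRX	DAXX	PML	SP100	BLM	TOP3A	RAD51	RAD52	POLD3	RFC1	PCNA	FEN1	SLX4	EME1	NR2F2	ZNF827	SMC5	SMC6	NSMCE2	MND1	PSMC3IP	BRCA1	MRE11A	RAD50	NBN	FXR1	HNRNPA1
mismatch repair	DNA mismatch repair	MLH1	MLH3	MSH2	MSH3	MSH6	PMS1	PMS2	EXO1	POLD1	POLD2	LIG1	RPA1	RPA2	RPA3
regulation of apoptosis	apoptotic programme regulation	TP53	BAX	BAK1	BCL2	BCL2L1	MCL1	BID	BBC3	PMAIP1	CASP3	CASP8	CASP9	APAF1	CYCS	XIAP	BIRC5	FAS	FADD
cell cycle	proliferation and mitotic cell cycle	CCNA2	CCNB1	CCNB2	CCNE1	CCND1	CDK1	CDK2	CDK4	CDK6	CDC20	CDC25A	PLK1	AURKA	AURKB	BUB1	BUB1B	MKI67	TOP2A	E2F1	MCM2	MCM3	MCM7	KIF11	TPX2
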