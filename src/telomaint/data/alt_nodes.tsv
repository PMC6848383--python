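# Alternative lengthening of telomeres (ALT) pathway: node table.
# Branches: chromatin (telomeric chromatin decompaction), APB
# (ALT-associated PML body formation), TERRA (TERRA induction and
# telomeric instability), HR1-HR3 (homologous recombination / break-induced
# repair: strand invasion, template-directed synthesis, resolution).
node	kind	branch	members
SUV39H1	gene	chromatin
SUV420H2	gene	chromatin
NR2F2	gene	chromatin
ZNF827	gene	chromatin
chromatin_decompaction	process	chromatin
PML	gene	APB
SP100	gene	APB
MRN	gene	APB	MRE11A;RAD50;NBN
SMC5_6	gene	APB	SMC5;SMC6;NSMCE2
FXR1	gene	APB
BRCA1	gene	APB
APB_formation	process	APB
ATRX	gene	TERRA
DAXX	gene	TERRA
HNRNPA1	gene	TERRA
TERRA_instability	process	TERRA
RAD51	gene	HR1
RAD52	gene	HR1
MND1	gene	HR1
PSMC3IP	gene	HR1
ATR	gene	HR1
CHEK1	gene	HR1
RPA	gene	HR1	RPA1;RPA2;RPA3
HR_step1	process	HR1
POLD3	gene	HR2
RFC1	gene	HR2
PCNA	gene	HR2
FEN1	gene	HR2
HR_step2	process	HR2
BLM	gene	HR3
TOP3A	gene	HR3
EME1	gene	HR3
SLX4	gene	HR3
HR_step3	process	HR3
ALT	sink
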