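# Alternative lengthening of telomeres (ALT) pathway: signed edge list.
# evidence: "literature" = role documented in the telomere-biology
# literature; "inferred" = wiring inferred during curation of this model.
source	target	sign	priority	evidence
SUV39H1	chromatin_decompaction	inhibit	1	literature
SUV420H2	chromatin_decompaction	inhibit	1	literature
NR2F2	chromatin_decompaction	activate	1	literature
ZNF827	chromatin_decompaction	activate	1	literature
PML	APB_formation	activate	1	literature
SP100	APB_formation	inhibit	1	literature
MRN	APB_formation	activate	1	literature
SMC5_6	APB_formation	activate	1	literature
FXR1	APB_formation	activate	1	inferred
BRCA1	APB_formation	activate	1	literature
ATRX	TERRA_instability	inhibit	1	literature
DAXX	TERRA_instability	inhibit	1	literature
HNRNPA1	TERRA_instability	activate	1	literature
chromatin_decompaction	HR_step1	activate	1	inferred
TERRA_instability	HR_step1	activate	1	inferred
APB_formation	HR_step1	activate	1	inferred
RAD51	HR_step1	activate	1	literature
RAD52	HR_step1	activate	1	literature
MND1	HR_step1	activate	1	literature
PSMC3IP	HR_step1	activate	1	literature
ATR	HR_step1	activate	1	literature
CHEK1	HR_step1	activate	1	literature
RPA	HR_step1	activate	1	literature
HR_step1	HR_step2	activate	1	inferred
POLD3	HR_step2	activate	1	literature
RFC1	HR_step2	activate	1	literature
PCNA	HR_step2	activate	1	literature
FEN1	HR_step2	activate	1	literature
HR_step2	HR_step3	activate	1	inferred
BLM	HR_step3	activate	1	literature
TOP3A	HR_step3	activate	1	literature
EME1	HR_step3	inhibit	1	literature
SLX4	HR_step3	inhibit	1	literature
HR_step3	ALT	activate	1	inferred
APB_formation	ALT	activate	1	literature
TERRA_instability	ALT	activate	1	inferred
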