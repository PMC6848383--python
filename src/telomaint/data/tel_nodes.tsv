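# Telomerase (TEL) telomere-maintenance pathway: node table.
# Branches: TERT (hTERT expression and maturation), TERC (hTR biogenesis),
# DKC1 (dyskerin/H-ACA complex), core (complex assembly, nuclear
# localisation and the sink).
node	kind	branch	members
TERT	gene	TERT
HSP90	gene	TERT	HSP90AA1;HSP90AB1
PTGES3	gene	TERT
HSPA1A	gene	TERT
STUB1	gene	TERT
hTERT_maturation	process	TERT
TERC	gene	TERC
PARN	gene	TERC
NAF1	gene	TERC
RBM7	gene	TERC
SRRT	gene	TERC
hTR_maturation	process	TERC
DKC1	gene	DKC1
NHP2	gene	DKC1
NOP10	gene	DKC1
GAR1	gene	DKC1
SHQ1	gene	DKC1
dyskerin_complex	process	DKC1
RUVBL1	gene	core
RUVBL2	gene	core
WRAP53	gene	core
IPO7	gene	core
RANBP2	gene	core
telomerase_assembly	process	core
nuclear_localization	process	core
TEL	sink
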