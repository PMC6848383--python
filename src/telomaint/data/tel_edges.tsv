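# Telomerase (TEL) telomere-maintenance pathway: signed edge list.
# evidence: "literature" = role documented in the telomere-biology
# literature; "inferred" = wiring inferred during curation of this model.
source	target	sign	priority	evidence
TERT	hTERT_maturation	activate	1	literature
HSP90	hTERT_maturation	activate	1	literature
PTGES3	hTERT_maturation	activate	1	literature
HSPA1A	hTERT_maturation	inhibit	1	literature
STUB1	hTERT_maturation	inhibit	1	literature
TERC	hTR_maturation	activate	1	literature
PARN	hTR_maturation	activate	1	literature
NAF1	hTR_maturation	activate	1	literature
RBM7	hTR_maturation	inhibit	1	literature
SRRT	hTR_maturation	inhibit	1	literature
DKC1	dyskerin_complex	activate	1	literature
NHP2	dyskerin_complex	activate	1	literature
NOP10	dyskerin_complex	activate	1	literature
GAR1	dyskerin_complex	activate	1	literature
SHQ1	dyskerin_complex	activate	1	literature
hTERT_maturation	telomerase_assembly	activate	1	inferred
hTR_maturation	telomerase_assembly	activate	1	inferred
dyskerin_complex	telomerase_assembly	activate	1	inferred
RUVBL1	telomerase_assembly	activate	1	literature
RUVBL2	telomerase_assembly	activate	1	literature
WRAP53	telomerase_assembly	activate	1	literature
telomerase_assembly	nuclear_localization	activate	1	inferred
IPO7	nuclear_localization	activate	1	literature
RANBP2	nuclear_localization	activate	1	literature
nuclear_localization	TEL	activate	1	inferred
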