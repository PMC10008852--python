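target_id	modality	role	drugs	nct	escat	approval	basket	drug_class	flags	notes
CD38	IHC	ANY	Daratumumab	m1C	IIA	EMA/FDA	BCT	anti-CD38 antibody	-	-
CD38	IHC	ANY	Isatuximab	m2A	IIA	EMA/FDA	BCT	anti-CD38 antibody	-	-
TP53	MUTATION	TSG	Eprenetapopt+Pembrolizumab	m2A	IC	FDA-FT	CC	p53 reactivator combination	-	-
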