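target_id	modality	role	drugs	nct	escat	approval	basket	drug_class	flags	notes
CD38	IHC	ANY	Daratumumab	m1C	IIA	EMA/FDA	BCT	anti-CD38 antibody	-	-
CD38	IHC	ANY	Isatuximab	m2A	IIA	EMA/FDA	BCT	anti-CD38 antibody	-	alternative anti-CD38 agent; lower evidence than daratumumab
CD30	IHC	ANY	Brentuximab vedotin	m1C	IIB	EMA/FDA	BCT	anti-CD30 antibody-drug conjugate	-	-
CD19	IHC	ANY	Tafasitamab	m2A	IIIA	EMA/FDA	BCT	anti-CD19 antibody	-	-
CD79B	IHC	ANY	Polatuzumab vedotin	m2A	IIIA	EMA/FDA	BCT	anti-CD79B antibody-drug conjugate	-	-
STAT3	MUTATION	ONCOGENE	Napabucasin	m2B	IC	FDA-FT	OTH	STAT3 inhibitor	-	-
NF1	MUTATION	TSG	Selumetinib	m2A	IIIA	EMA/FDA	RME	MEK inhibitor	-	NF1 loss activates RAS-MAPK signalling
ERBB2	MUTATION	ONCOGENE	Pertuzumab+Trastuzumab+Docetaxel	m2A	IIIA	EMA/FDA	TK	anti-HER2 combination	-	combination targeting one aberration; counted once
PIK3CD	MUTATION	ONCOGENE	Idelalisib	m2B	IIIA	EMA/FDA	PAM	PI3K-delta inhibitor	-	-
TP53	MUTATION	TSG	Eprenetapopt+Pembrolizumab	m2A	IC	FDA-FT	CC	p53 reactivator combination	-	-
TP53	MUTATION	TSG	Palbociclib	m2B	IIIA	EMA/FDA	CC	CDK4/6 inhibitor	-	historical rationale; withheld by the TP53 resistance rule
TP53	MUTATION	TSG	Palbociclib+Abemaciclib	m2B	IIIA	NONE	CC	CDK4/6 inhibitor	exclusion	TP53 loss-of-function promotes resistance to CDK4/6 inhibition
KIT	MUTATION	ONCOGENE	Ripretinib	m2A	IIIA	EMA/FDA	TK	KIT inhibitor	-	-
ROS1	MUTATION	ONCOGENE	Pembrolizumab	m2B	IIIA	EMA/FDA	IE	immune checkpoint inhibitor	-	ROS1 alteration propagates immune escape; checkpoint blockade rationale
MTOR	MUTATION	ONCOGENE	Everolimus+Pazopanib	m2A	IIIA	EMA/FDA	PAM	mTOR inhibitor combination	-	-
NRAS	MUTATION	ONCOGENE	Ulixertinib	m2A	IC	FDA-FT	RME	ERK inhibitor	-	-
IDH2	MUTATION	ONCOGENE	Enasidenib+Azacitidine	m2A	IIIA	FDA	TK	IDH2 inhibitor combination	-	-
TET2	MUTATION	TSG	Azacitidine	m2B	IIIA	EMA/FDA	OTH	hypomethylating agent	-	-
IDH1	MUTATION	ONCOGENE	Ivosidenib+Azacitidine	m2A	IC	FDA	TK	IDH1 inhibitor combination	-	-
FGFR2	MUTATION	ONCOGENE	Bemarituzumab	m2A	IIIA	EMA-FT	TK	anti-FGFR2b antibody	-	-
TMB	TMB_HIGH	ANY	Pembrolizumab	m1C	IC	FDA	IE	immune checkpoint inhibitor	-	immunotherapy rationale for TMB >= 10 mut/Mb
MSI	MSI_HIGH	ANY	Pembrolizumab	m1C	IC	FDA	IE	immune checkpoint inhibitor	-	immunotherapy rationale for MSI-high status
BRCANESS	BRCANESS	ANY	Olaparib	m2B	IIIA	EMA/FDA	OTH	PARP inhibitor	-	PARP inhibition rationale for positive BRCAness score
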