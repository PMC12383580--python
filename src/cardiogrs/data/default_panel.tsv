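rsid	gene	risk_allele
rs4343	ACE	G
rs283411	ADH1C	T
rs5751876	ADORA2A	T
rs1042713	ADRB2	A
rs5128	APOC3	G
rs429358	APOE	C
rs7412	APOE	C
rs1801260	CLOCK	C
rs762551	CYP1A2	C
rs174570	FADS2	T
rs9930506	FTO	G
rs9939609	FTO	A
rs1800588	LIPC	T
rs17782313	MC4R	C
rs4988235	MCM6	G
rs5400	SLC2A2	T
rs12255372	TCF7L2	T
rs7903146	TCF7L2	T
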