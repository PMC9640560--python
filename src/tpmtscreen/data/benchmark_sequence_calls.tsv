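# Sequence-tool calls (D = deleterious, N = neutral, NA = not available) for the
# experimentally characterized benchmark variants.
rsid	variant	PROVEAN	PANTHER	PolyPhen-2	Mutation Assessor	Meta-SNP	PMut	PredictSNP1	SNAP2	SuSPect	SNPs&GO	PhD-SNP	SIFT
rs9333569	M1V	N	D	N	NA	N	N	N	N	N	N	N	D
rs72552742	E28V	D	N	N	N	N	D	N	D	N	N	D	D
NA	Q42E	N	N	N	N	N	N	N	N	N	N	N	N
rs72552740	L49S	D	D	D	D	D	D	D	D	D	D	D	D
rs200591577	L69V	D	D	D	D	D	D	D	D	D	D	D	D
rs777686348	G71R	D	D	D	D	D	D	D	D	D	D	D	D
rs281874771	A73V	D	D	D	N	D	D	D	D	D	N	N	D
rs1800462	A80P	D	D	D	D	D	D	D	D	D	D	D	D
rs111901354	R82W	D	N	D	N	D	N	D	D	D	D	D	D
NA	Y107D	D	D	D	N	D	D	D	D	N	D	D	D
rs115106679	E114K	N	N	D	N	N	N	N	N	N	N	N	D
rs200220210	S125L	D	N	N	N	N	N	N	N	N	N	N	N
rs72552738	C132Y	D	D	N	N	D	D	D	N	D	D	D	D
rs72552737	G144R	D	D	D	N	D	N	D	D	N	D	D	D
rs1800460	A154T	D	N	N	D	D	D	D	D	D	D	D	D
rs112339338	R163C	D	D	D	D	D	D	D	D	D	D	D	D
rs144041067	R163H	D	D	D	N	D	N	D	D	D	N	D	N
NA	R163P	D	D	D	D	D	D	D	D	D	D	D	D
rs201695576	Y166C	D	D	D	D	D	D	D	D	D	D	D	D
rs74423290	A167G	D	N	N	N	N	D	D	D	D	N	D	N
rs72556347	F208L	N	D	N	N	N	N	N	N	N	N	D	N
rs377085266	C212R	D	D	D	N	D	D	D	D	D	D	D	N
rs150900439	K238E	N	N	N	N	N	N	N	N	N	N	N	D
rs1142345	Y240C	D	D	D	D	D	D	D	D	D	N	D	D
rs1142345	Y240S	D	D	D	N	N	D	D	N	D	D	D	D
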