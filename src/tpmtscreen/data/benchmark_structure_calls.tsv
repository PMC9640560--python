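# Structure-tool calls for the benchmark variants (D = destabilizing / decrease,
# SD = strongly decrease, N = neutral). Residues 1-16 are absent from the
# crystal structure, so M1V has no structural predictions (NA).
rsid	variant	CUPSAT	DUET	I-Mutant 3.0	MUpro	INPS-MD	PoPMuSiC	HoTMuSiC	SNPMuSiC
rs9333569	M1V	NA	NA	NA	NA	NA	NA	NA	NA
rs72552742	E28V	D	N	N	D	N	D	D	N
NA	Q42E	D	N	N	N	N	D	D	N
rs72552740	L49S	D	D	D	D	D	D	D	D
rs200591577	L69V	D	N	D	D	D	D	D	N
rs777686348	G71R	D	D	D	D	N	D	D	D
rs281874771	A73V	D	D	N	N	N	D	D	D
rs1800462	A80P	D	D	D	D	D	D	D	D
rs111901354	R82W	D	D	D	N	N	D	D	N
NA	Y107D	D	D	D	D	D	D	D	D
rs115106679	E114K	D	N	D	D	N	D	D	N
rs200220210	S125L	D	N	N	N	N	D	D	D
rs72552738	C132Y	N	D	D	D	D	D	D	D
rs72552737	G144R	D	D	D	D	N	D	D	D
rs1800460	A154T	N	D	D	D	N	D	D	D
rs112339338	R163C	N	D	D	D	N	D	D	D
rs144041067	R163H	D	D	D	D	D	D	D	N
NA	R163P	N	D	D	D	D	D	D	D
rs201695576	Y166C	N	D	D	D	D	D	D	D
rs74423290	A167G	D	D	D	D	D	D	D	D
rs72556347	F208L	D	D	D	D	D	D	D	D
rs377085266	C212R	D	D	D	D	D	D	D	D
rs150900439	K238E	N	N	D	D	N	D	D	N
rs1142345	Y240C	D	D	D	D	N	D	D	D
rs1142345	Y240S	D	D	D	D	D	SD	D	D
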