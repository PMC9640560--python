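rsid	variant	PROVEAN	PANTHER	PolyPhen-2	Mutation Assessor	Meta-SNP	PMut	PredictSNP1	SNAP2	SuSPect	SNPs&GO	PhD-SNP	SIFT
rs72552741	W33G	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs200695400	F40S	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs1446592306	F40L	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs757081801	H41R	Deleterious	Probably damaging	Possibly damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs762702707	H46R	Deleterious	Probably damaging	Probably damaging	Medium	Neutral	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs72552740	L49S	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs757971326	H52D	Deleterious	Possibly damaging	Possibly damaging	Medium	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs1236222449	F66I	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Neutral	Neutral	Disease	Neutral
rs1368439131	P68L	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs1784276391	P68S	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs200591577	L69V	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs200591577	L69F	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs777686348	G71R	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs778578091	E75K	Deleterious	Possibly damaging	Probably damaging	Medium	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs1200214781	M76K	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs1256618794	W78C	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs753277177	W78R	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs1800462	A80P	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs111901354	R82G	Deleterious	Probably benign	Probably damaging	Medium	Disease	Disease	Deleterious	Effect	Neutral	Disease	Disease	Deleterious
rs111901354	R82W	Deleterious	Probably benign	Probably damaging	Medium	Disease	Neutral	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs1293957844	G83V	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs1235431245	H84D	Deleterious	Probably damaging	Probably damaging	High	Disease	Neutral	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs1582044292	H84L	Deleterious	Probably damaging	Probably damaging	Medium	Disease	Neutral	Deleterious	Effect	Deleterious	Disease	Disease	Neutral
rs753545734	G88S	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs753545734	G88C	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs1784191846	V89E	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs1681788109	E90V	Deleterious	Possibly damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs1474060016	L105R	Deleterious	Possibly damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Neutral	Disease	Disease	Deleterious
rs886061266	I112N	Deleterious	Probably benign	Probably damaging	Medium	Disease	Disease	Deleterious	Effect	Neutral	Disease	Disease	Deleterious
rs1396619437	S129P	Deleterious	Probably benign	Probably damaging	Medium	Disease	Disease	Deleterious	Effect	Neutral	Disease	Disease	Deleterious
rs72552738	C132Y	Deleterious	Probably damaging	Possibly damaging	Medium	Disease	Disease	Deleterious	Neutral	Deleterious	Disease	Disease	Deleterious
rs72552737	G144R	Deleterious	Probably damaging	Probably damaging	Medium	Disease	Neutral	Deleterious	Effect	Neutral	Disease	Disease	Deleterious
rs1310627040	I149T	Deleterious	Probably damaging	Probably damaging	Medium	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs1447033392	W150G	Deleterious	Probably damaging	Probably damaging	Medium	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs1354851110	D151Y	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs1408113946	R152T	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs1800460	A154T	Deleterious	Probably benign	Possibly damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs1158437171	L155S	Deleterious	Possibly damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs112339338	R163S	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs112339338	R163C	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs201695576	Y166C	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs1386533390	L182P	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs1783991755	V184D	Deleterious	Probably benign	Probably damaging	Medium	Disease	Disease	Deleterious	Effect	Neutral	Disease	Disease	Deleterious
rs747307984	L185R	Deleterious	Probably benign	Possibly damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs1554137341	Y187C	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs758437011	G194S	Deleterious	Probably damaging	Probably damaging	High	Neutral	Disease	Deleterious	Effect	Deleterious	Neutral	Disease	Deleterious
rs79901429	I204T	Deleterious	Probably benign	Probably damaging	Medium	Disease	Disease	Deleterious	Effect	Deleterious	Neutral	Disease	Deleterious
rs761626260	L207W	Deleterious	Probably damaging	Probably damaging	Medium	Disease	Neutral	Deleterious	Effect	Deleterious	Disease	Disease	Neutral
rs377085266	C212R	Deleterious	Probably damaging	Probably damaging	Medium	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Neutral
rs780065109	G231V	Deleterious	Probably damaging	Probably damaging	Medium	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs781105138	L235P	Deleterious	Probably benign	Probably damaging	Medium	Disease	Disease	Deleterious	Effect	Deleterious	Disease	Disease	Deleterious
rs1142345	Y240C	Deleterious	Probably damaging	Probably damaging	High	Disease	Disease	Deleterious	Effect	Deleterious	Neutral	Disease	Deleterious
rs1142345	Y240S	Deleterious	Probably damaging	Probably damaging	Medium	Neutral	Disease	Deleterious	Neutral	Deleterious	Disease	Disease	Deleterious
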