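# Study-level evidence for the benchmark variants: VD = very dangerous,
# D = dangerous, one report per study (opaque study identifiers).
# extremely_deleterious marks the high-confidence 12-member subset (VD in
# multiple studies, or VD with corroborating further reports - Y240S's
# corroboration comes from literature outside this evidence table).
# printed_total is the published cumulative 20-tool deleterious count,
# kept as metadata; three entries (A167G, Y240C, Y240S) are internally
# inconsistent with their own published calls by one.
variant	rsid	evidence	extremely_deleterious	printed_total
M1V	rs9333569	D:84;VD:77	false	NA
E28V	rs72552742	D:77;D:88;D:91	false	9
Q42E	NA	D:77;D:81	false	3
L49S	rs72552740	VD:77;VD:85;VD:88	true	20
L69V	rs200591577	VD:75;VD:83	true	18
G71R	rs777686348	VD:77;VD:81	true	19
A73V	rs281874771	VD:89	false	14
A80P	rs1800462	VD:77;VD:78;VD:87	true	20
R82W	rs111901354	VD:74	false	14
Y107D	NA	VD:76	false	18
E114K	rs115106679	VD:74;VD:86	true	7
S125L	rs200220210	D:77;D:88;D:91	false	5
C132Y	rs72552738	D:77;D:91;VD:80	true	16
G144R	rs72552737	D:77;D:88;D:91;VD:15	true	16
A154T	rs1800460	VD:11;VD:73;VD:78;VD:82;VD:87;VD:89	true	16
R163C	rs112339338	VD:74	false	18
R163H	rs144041067	VD:72;VD:77;VD:81	true	15
R163P	NA	VD:75;VD:77	true	19
Y166C	rs201695576	D:79	false	19
A167G	rs74423290	D:92	false	15
F208L	rs72556347	D:90	false	10
C212R	rs377085266	VD:83	false	18
K238E	rs150900439	D:75;D:77	false	5
Y240C	rs1142345	VD:9;VD:11;VD:73;VD:78;VD:82;VD:87	true	19
Y240S	rs1142345	VD:20	true	18
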