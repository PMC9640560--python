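# CScape / CScape-somatic coding p-scores for the five candidate mutations.
# Scores above 0.5 are called oncogenic / driver; HC = high confidence
# (metadata only, no numeric threshold is published for it).
variant	rsid	CScape	CScape_message	CScape-somatic	CScape_somatic_message
W33G	rs72552741	0.898663	Oncogenic (HC)	0.907987	Driver (HC)
W78R	rs753277177	0.695307	Oncogenic	0.820811	Driver
V89E	rs1784191846	0.807748	Oncogenic	0.781448	Driver
W150G	rs1447033392	0.860191	Oncogenic	0.728649	Driver
L182P	rs1386533390	0.519117	Oncogenic	0.841487	Driver
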