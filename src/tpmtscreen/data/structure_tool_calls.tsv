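# Structure-based stability calls for the six stage-1 survivors that passed the
# strict 6-of-8 structural vote. The aux_* columns carry sub-predictor
# components (mCSM / SDM / DUET constituents) that do not vote.
rsid	variant	CUPSAT	DUET	I-Mutant 3.0	MUpro	INPS-MD	PoPMuSiC	HoTMuSiC	SNPMuSiC	aux_mCSM	aux_SDM	aux_DUET
rs72552741	W33G	Destabilising	Destabilizing	Destabilizing	Destabilizing	Decrease	Strongly Decrease	Strongly Decrease	Strongly Decrease	Decrease	Decrease	Decrease
rs753277177	W78R	Destabilising	Destabilizing	Destabilizing	Destabilizing	Decrease	Decrease	Decrease	Strongly Decrease	Decrease	Decrease	Decrease
rs1784191846	V89E	Destabilising	Destabilizing	Destabilizing	Destabilizing	Decrease	Strongly Decrease	Strongly Decrease	Decrease	Decrease	Decrease	Decrease
rs1447033392	W150G	Destabilising	Destabilizing	Destabilizing	Destabilizing	Decrease	Strongly Decrease	Strongly Decrease	Strongly Decrease	Decrease	Decrease	Decrease
rs1386533390	L182P	Destabilising	Destabilizing	Destabilizing	Destabilizing	Decrease	Strongly Decrease	Strongly Decrease	Decrease	Decrease	Decrease	Decrease
rs1142345	Y240S	Destabilising	Destabilizing	Destabilizing	Destabilizing	Decrease	Strongly Decrease	Decrease	Decrease	Decrease	Decrease	Decrease
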