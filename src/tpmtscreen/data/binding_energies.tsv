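# MM-PBSA binding free energies (kJ/mol) of the ligand-bound systems, mean and
# standard deviation over the analysed trajectory window. Consumed as numeric
# inputs only; the underlying molecular-dynamics work is out of scope here.
system	vdw_mean	vdw_sd	elec_mean	elec_sd	polar_mean	polar_sd	sasa_mean	sasa_sd	binding_mean	binding_sd
WT-SAH	-215.76	11.86	-47.82	9.34	146.29	12.92	-21.48	0.92	-138.77	14.68
W33G	-0.004	0.00	0.00	0.00	16.21	50.22	-0.40	3.47	15.81	50.25
W78R	-0.005	0.00	0.00	0.00	5.13	61.70	-0.47	3.52	4.65	61.61
V89E	-0.005	0.00	0.00	0.00	-17.84	47.13	0.39	3.64	-17.45	47.15
W150G	-0.005	0.00	0.00	0.00	-28.27	41.29	-0.52	3.85	-28.8	41.57
L182P	-210.10	11.34	-60.55	10.00	189.25	14.48	-20.84	0.87	-102.24	13.42
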