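# Conservation components at the five mutated residues: ConSurf colour score
# (1-9), number of species conserving the residue in a 10-sequence alignment,
# and number of the 13 most dissimilar homologues conserving it.
# The published text fixes: W150G consurf = 8, L182P consurf = 6, the other
# three in 8-9; msa = 10 for all five; cdd >= 7 for all but W150G. Exact
# consurf values for W33G/W78R/V89E and all cdd values are SYNTHETIC
# stand-ins consistent with those constraints (supplementary data not
# reproduced here).
mutation	consurf	msa	cdd
W33G	9	10	13
W78R	9	10	11
V89E	9	10	10
W150G	8	10	5
L182P	6	10	9
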