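# SYNTHETIC stand-ins for feature values only available in supplementary
# material: absolute binding-pocket volume change (A^3, summed over affected
# pockets for W33G and L182P) and residue distance to the nearest predicted
# PTM site. Published anchors: pocket impact is large for W33G and W150G,
# negligible for W78R and V89E, intermediate (several pockets) for L182P;
# PTM distances W33G->T38 = 5, V89E->S92 = 3, L182P->Y180 = 2 are printed,
# W78R and W150G distances are synthetic.
mutation	pocket_volume_change	ptm_distance
W33G	1100	5
W78R	40	7
V89E	60	3
W150G	750	6
L182P	300	2
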