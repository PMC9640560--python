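# Functional-class counts of the 10,305 TPMT SNPs catalogued in dbSNP.
class	count
intron	8610
3'UTR	787
5'UTR	398
missense	213
synonymous	71
frameshift	20
nonsense	11
other	195
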