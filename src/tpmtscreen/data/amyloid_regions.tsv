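# Predicted amyloid-forming residue regions of TPMT (inclusive intervals).
start	end
64	69
86	89
100	101
127	138
147	149
154	158
170	175
178	187
207	217
231	243
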