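# Unsaturated fatty-acid biosynthesis steps scored as product/substrate indices.
# kind: desaturation | elongation | elongation+b-oxidation (the DHA step is the
# composite C22:5n3 -> C22:6n3 route via C24 intermediates, attributed to the
# rate-limiting elongase ELOVL2; the intermediates themselves are not modeled).
# genes is a ;-separated list of symbols annotated to the step.
substrate	product	genes	kind
16:0	16:1	SCD	desaturation
18:0	18:1	SCD	desaturation
16:0	18:0	PTPLB;PECR	elongation
18:0	20:0	PTPLB;PECR;ELOVL3	elongation
20:0	22:0	PTPLB;PECR;ELOVL3	elongation
20:3n6	20:4n6	FADS1	desaturation
22:5n3	22:6n3	ELOVL2	elongation+b-oxidation
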