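metal	intercept_a	exponent_b	ratio_c	source	n_significant
Mo	1.890356787	-1.518897816	1.606082378	reference	3
Ni	2.167059786	-1.624918705	0.8423479703	reference	4
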