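metal	cluster_label	fraction_id
Mo	1	S01F013
Mo	1	S01F014
Mo	1	S01F015
Mo	1	S02F010
Mo	1	S02F012
Mo	1	S02F013
Ni	1	S01F009
Ni	1	S01F011
Ni	1	S01F012
Ni	1	S01F013
Ni	1	S01F014
Ni	1	S02F009
Ni	1	S02F010
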