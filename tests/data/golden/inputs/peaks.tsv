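peak_id	metal	separation_id	fraction_id
Mo_S01_13	Mo	S01	S01F013
Mo_S01_13	Mo	S01	S01F014
Mo_S01_13	Mo	S01	S01F015
Mo_S02_10	Mo	S02	S02F010
Mo_S02_10	Mo	S02	S02F011
Mo_S02_10	Mo	S02	S02F012
Mo_S02_10	Mo	S02	S02F013
Ni_S01_12	Ni	S01	S01F012
Ni_S01_12	Ni	S01	S01F013
Ni_S01_12	Ni	S01	S01F014
Ni_S02_9	Ni	S02	S02F009
Ni_S02_9	Ni	S02	S02F010
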