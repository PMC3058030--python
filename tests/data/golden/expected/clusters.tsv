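metal	protein_id	cluster_label
Mo	MP_Mo_01	0
Mo	MP_Mo_02	1
Mo	MP_Mo_03	1
Ni	MP_Mo_01	0
Ni	MP_Ni_01	1
Ni	MP_Ni_02	1
Ni	MP_Ni_03	0
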