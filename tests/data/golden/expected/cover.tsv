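metal	rank	protein_id	peaks_newly_covered
Mo	1	MP_Mo_03	2
Ni	1	MP_Ni_01	2
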