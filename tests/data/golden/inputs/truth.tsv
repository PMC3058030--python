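protein_id	metal
MP_Mo_01	Mo
MP_Mo_02	Mo
MP_Mo_03	Mo
MP_Ni_01	Ni
MP_Ni_02	Ni
MP_Ni_03	Ni
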