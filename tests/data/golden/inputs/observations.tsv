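fraction_id	protein_id	peptide_count
S01F000	BG_0001	1
S01F004	BG_0010	3
S01F004	MP_Ni_03	2
S01F006	BG_0004	1
S01F009	MP_Ni_02	6
S01F011	MP_Ni_01	3
S01F012	MP_Ni_01	3
S01F012	MP_Ni_02	3
S01F012	MP_Ni_03	3
S01F013	MP_Mo_01	2
S01F013	MP_Mo_02	2
S01F013	MP_Mo_03	1
S01F013	MP_Ni_01	1
S01F013	MP_Ni_02	2
S01F013	MP_Ni_03	1
S01F014	MP_Mo_01	1
S01F014	MP_Mo_02	7
S01F014	MP_Mo_03	3
S01F014	MP_Ni_01	4
S01F014	MP_Ni_02	1
S01F014	MP_Ni_03	3
S01F015	MP_Mo_01	2
S01F015	MP_Mo_02	2
S01F015	MP_Mo_03	5
S01F016	BG_0008	3
S01F019	BG_0008	1
S02F000	BG_0006	3
S02F002	BG_0010	2
S02F003	BG_0006	5
S02F003	BG_0012	2
S02F004	BG_0001	1
S02F007	BG_0001	1
S02F007	BG_0003	5
S02F008	BG_0005	3
S02F009	BG_0009	3
S02F009	MP_Ni_01	3
S02F009	MP_Ni_02	2
S02F010	BG_0012	3
S02F010	MP_Mo_01	2
S02F010	MP_Mo_03	2
S02F010	MP_Ni_01	2
S02F010	MP_Ni_02	3
S02F011	MP_Mo_01	3
S02F012	MP_Mo_03	4
S02F013	MP_Mo_02	1
S02F013	MP_Mo_03	3
S02F013	MP_Ni_03	6
S02F019	BG_0002	4
S02F019	BG_0010	3
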