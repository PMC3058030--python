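fraction_id	separation_id	order_index	parent_fraction_id	level
S01F000	S01	0	.	2
S01F001	S01	1	.	2
S01F002	S01	2	.	2
S01F003	S01	3	.	2
S01F004	S01	4	.	2
S01F005	S01	5	.	2
S01F006	S01	6	.	2
S01F007	S01	7	.	2
S01F008	S01	8	.	2
S01F009	S01	9	.	2
S01F010	S01	10	.	2
S01F011	S01	11	.	2
S01F012	S01	12	.	2
S01F013	S01	13	.	2
S01F014	S01	14	.	2
S01F015	S01	15	.	2
S01F016	S01	16	.	2
S01F017	S01	17	.	2
S01F018	S01	18	.	2
S01F019	S01	19	.	2
S02F000	S02	0	.	2
S02F001	S02	1	.	2
S02F002	S02	2	.	2
S02F003	S02	3	.	2
S02F004	S02	4	.	2
S02F005	S02	5	.	2
S02F006	S02	6	.	2
S02F007	S02	7	.	2
S02F008	S02	8	.	2
S02F009	S02	9	.	2
S02F010	S02	10	.	2
S02F011	S02	11	.	2
S02F012	S02	12	.	2
S02F013	S02	13	.	2
S02F014	S02	14	.	2
S02F015	S02	15	.	2
S02F016	S02	16	.	2
S02F017	S02	17	.	2
S02F018	S02	18	.	2
S02F019	S02	19	.	2
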