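protein_id	metal	f	f_m	f_p	f_pm	score	ln_score
BG_0002	Mo	40	7	1	0	1	0
BG_0003	Mo	40	7	1	0	1	0
BG_0005	Mo	40	7	1	0	1	0
BG_0006	Mo	40	7	2	0	1	0
BG_0008	Mo	40	7	2	0	1	0
BG_0009	Mo	40	7	1	0	1	0
BG_0010	Mo	40	7	3	0	1	0
BG_0012	Mo	40	7	2	1	0.3230769231	-1.129864832
MP_Mo_01	Mo	40	7	5	5	3.19145056e-05	-10.35244993
MP_Mo_02	Mo	40	7	4	4	0.0003829740672	-7.867543281
MP_Mo_03	Mo	40	7	6	6	1.823686034e-06	-13.21465081
MP_Ni_01	Mo	40	7	6	3	0.05474705475	-2.905031706
MP_Ni_02	Mo	40	7	6	3	0.05474705475	-2.905031706
MP_Ni_03	Mo	40	7	5	3	0.02987197724	-3.510834454
BG_0002	Ni	40	5	1	0	1	0
BG_0003	Ni	40	5	1	0	1	0
BG_0005	Ni	40	5	1	0	1	0
BG_0006	Ni	40	5	2	0	1	0
BG_0008	Ni	40	5	2	0	1	0
BG_0009	Ni	40	5	1	1	0.125	-2.079441542
BG_0010	Ni	40	5	3	0	1	0
BG_0012	Ni	40	5	2	1	0.2371794872	-1.438938095
MP_Mo_01	Ni	40	5	5	3	0.009309917205	-4.676675081
MP_Mo_02	Ni	40	5	4	2	0.06899004267	-2.673793094
MP_Mo_03	Ni	40	5	6	3	0.01783564941	-4.026556048
MP_Ni_01	Ni	40	5	6	5	9.118430171e-06	-11.6052129
MP_Ni_02	Ni	40	5	6	5	9.118430171e-06	-11.6052129
MP_Ni_03	Ni	40	5	5	3	0.009309917205	-4.676675081
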