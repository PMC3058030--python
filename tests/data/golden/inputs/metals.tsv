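fraction_id	metal	replicate	concentration
S01F000	Mo	1	1.0523948
S01F000	Mo	2	0.77327528
S01F001	Mo	1	1.0012669
S01F001	Mo	2	0.99515876
S01F002	Mo	1	0.81555836
S01F002	Mo	2	1.0992174
S01F003	Mo	1	0.9749165
S01F003	Mo	2	0.94459673
S01F004	Mo	1	1.1253443
S01F004	Mo	2	1.1225857
S01F005	Mo	1	0.75139668
S01F005	Mo	2	0.96774796
S01F006	Mo	1	0.89562132
S01F006	Mo	2	1.119109
S01F007	Mo	1	0.6729174
S01F007	Mo	2	1.3037931
S01F008	Mo	1	0.75957725
S01F008	Mo	2	0.85776939
S01F009	Mo	1	0.68089197
S01F009	Mo	2	1.0208337
S01F010	Mo	1	0.93597331
S01F010	Mo	2	0.89461233
S01F011	Mo	1	0.76290768
S01F011	Mo	2	1.0056098
S01F012	Mo	1	1.0346999
S01F012	Mo	2	0.77512965
S01F013	Mo	1	8.0919886
S01F013	Mo	2	6.9943664
S01F014	Mo	1	7.5595447
S01F014	Mo	2	7.5456867
S01F015	Mo	1	4.7655195
S01F015	Mo	2	9.372917
S01F016	Mo	1	0.88135544
S01F016	Mo	2	1.2302187
S01F017	Mo	1	0.97120706
S01F017	Mo	2	0.75448135
S01F018	Mo	1	1.0028336
S01F018	Mo	2	0.83779396
S01F019	Mo	1	0.72423322
S01F019	Mo	2	1.1146092
S02F000	Mo	1	0.89205663
S02F000	Mo	2	0.66087302
S02F001	Mo	1	0.80783421
S02F001	Mo	2	0.89463673
S02F002	Mo	1	0.83544207
S02F002	Mo	2	0.96186875
S02F003	Mo	1	1.2098451
S02F003	Mo	2	1.2577591
S02F004	Mo	1	0.83565762
S02F004	Mo	2	1.1240303
S02F005	Mo	1	0.97428537
S02F005	Mo	2	0.91905214
S02F006	Mo	1	1.1682842
S02F006	Mo	2	0.91155446
S02F007	Mo	1	0.87355178
S02F007	Mo	2	0.93317773
S02F008	Mo	1	0.95912674
S02F008	Mo	2	1.3259282
S02F009	Mo	1	1.0022688
S02F009	Mo	2	0.90088528
S02F010	Mo	1	7.9443634
S02F010	Mo	2	7.3867633
S02F011	Mo	1	6.1547149
S02F011	Mo	2	8.4119953
S02F012	Mo	1	7.963831
S02F012	Mo	2	7.659246
S02F013	Mo	1	10.267007
S02F013	Mo	2	7.5440606
S02F014	Mo	1	0.72179776
S02F014	Mo	2	0.786437
S02F015	Mo	1	1.1625126
S02F015	Mo	2	0.9783458
S02F016	Mo	1	1.0040349
S02F016	Mo	2	0.8981141
S02F017	Mo	1	0.86359742
S02F017	Mo	2	1.2353226
S02F018	Mo	1	1.4572579
S02F018	Mo	2	1.1159753
S02F019	Mo	1	1.140366
S02F019	Mo	2	0.97590327
S01F000	Ni	1	1.1193602
S01F000	Ni	2	1.1441509
S01F001	Ni	1	0.91675147
S01F001	Ni	2	1.0063435
S01F002	Ni	1	1.2077451
S01F002	Ni	2	0.723273
S01F003	Ni	1	0.97953266
S01F003	Ni	2	1.2558012
S01F004	Ni	1	1.1006754
S01F004	Ni	2	1.3046157
S01F005	Ni	1	0.75937337
S01F005	Ni	2	0.96788451
S01F006	Ni	1	1.0502696
S01F006	Ni	2	0.92880419
S01F007	Ni	1	0.70191286
S01F007	Ni	2	0.95002141
S01F008	Ni	1	0.65528084
S01F008	Ni	2	0.80837302
S01F009	Ni	1	0.92319977
S01F009	Ni	2	1.218909
S01F010	Ni	1	0.82050605
S01F010	Ni	2	0.88062282
S01F011	Ni	1	1.0129623
S01F011	Ni	2	0.9706899
S01F012	Ni	1	12.236065
S01F012	Ni	2	6.7041385
S01F013	Ni	1	6.6533128
S01F013	Ni	2	6.9298786
S01F014	Ni	1	6.9328017
S01F014	Ni	2	6.0908502
S01F015	Ni	1	1.0212918
S01F015	Ni	2	1.2577726
S01F016	Ni	1	1.0811519
S01F016	Ni	2	0.95110939
S01F017	Ni	1	0.94691476
S01F017	Ni	2	1.1873013
S01F018	Ni	1	0.94139426
S01F018	Ni	2	0.98317168
S01F019	Ni	1	1.1269411
S01F019	Ni	2	0.85459162
S02F000	Ni	1	1.0869257
S02F000	Ni	2	0.91914828
S02F001	Ni	1	0.79905796
S02F001	Ni	2	0.87760406
S02F002	Ni	1	0.96532389
S02F002	Ni	2	0.98212752
S02F003	Ni	1	0.98745725
S02F003	Ni	2	0.91034737
S02F004	Ni	1	0.7957718
S02F004	Ni	2	0.92403298
S02F005	Ni	1	1.0323613
S02F005	Ni	2	0.74630097
S02F006	Ni	1	0.82735456
S02F006	Ni	2	0.83577161
S02F007	Ni	1	1.1887471
S02F007	Ni	2	1.3606504
S02F008	Ni	1	1.0187348
S02F008	Ni	2	0.8585221
S02F009	Ni	1	7.9846236
S02F009	Ni	2	6.3666672
S02F010	Ni	1	6.9781416
S02F010	Ni	2	8.386607
S02F011	Ni	1	0.9578155
S02F011	Ni	2	1.295749
S02F012	Ni	1	0.66017625
S02F012	Ni	2	0.73523248
S02F013	Ni	1	0.78374091
S02F013	Ni	2	0.94091123
S02F014	Ni	1	1.0536362
S02F014	Ni	2	0.86520965
S02F015	Ni	1	0.64329205
S02F015	Ni	2	0.69186355
S02F016	Ni	1	1.1595753
S02F016	Ni	2	1.1342097
S02F017	Ni	1	0.69391129
S02F017	Ni	2	0.9760385
S02F018	Ni	1	1.1391197
S02F018	Ni	2	0.99455303
S02F019	Ni	1	0.82939857
S02F019	Ni	2	0.84484696
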