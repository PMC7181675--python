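chromosome	start_snp	start_bp	end_bp	length_bp	n_snps	p_value	population
5	BovineHD0500016748	59767596	99577125	39809529	9680	0.004010498	Island
5	BovineHD0500028813	100575807	117357424	16781617	4362	3.02967E-05	Island
7	BovineHD0700014968	51524490	79119815	27595325	6783	0.000868087	Island
8	BovineHD0800022594	75480001	110042671	34562670	7518	0.000855569	Island
13	BovineHD1300000156	921869	5332272	4410403	995	0.006151847	Island
15	BovineHD1500008015	29876619	51078741	21202122	5538	0.002800973	Island
15	BovineHD1500023615	81113269	85272311	4159042	1115	0.00151371	Non-Island
24	BovineHD2400000046	318334	62643699	62325365	15655	5.48781E-06	Island
27	BovineHD2700002147	6820125	28454147	21634022	5382	4.43187E-07	Island
29	BovineHD2900000137	988412	2010551	1022139	249	0.003766464	Non-Island
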