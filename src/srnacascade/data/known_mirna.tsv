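mirna	sequence	count_gp	count_tg	normalized_printed	log2_printed	combined_star_row
hvu-miR5048	UAUUUGCAGGUUUUAGGUCUAA	4547	2106	2912.955844	-0.642431171	0
hvu-miR159a/b+star	UUUGGAUUGAAGGGAGCUCUGGAGCTCCTATCATTCCAATGA	22465	42602	5892.303845	1.391473899	1
hvu-miR444b	UGCAGUUGCUGUCUCAAGCUU	64	30	41.4950975	-0.625131008	0
hvu-miR1120	ACAUUCUUAUAUUAUGGGACGGAG	387	94	130.0179722	-1.573622508	0
hvu-miR444a	UUGCUGCCUCAAGCUUGCUGC	1	0	0	NUM	0
hvu-miR156	UGACAGAAGAGAGUGAGCACA	140769	213440	295223.787	1.068479308	0
hvu-miR1436	ACAUUAUGGGACGGAGGGAGU	8	2	2.766339833	-1.532021604	0
hvu-miR5050	UUGAGGUCGUUCAACCAGCAA	57	27	37.34558775	-0.610024116	0
hvu-miR5051+star	UUUGGCACCUUGAAACUGGGACCAGTTTCAAGGTTTCAAAGC	41	50	6.915849583	0.789906491	1
hvu-miR171	UGAUUGAGCCGUGCCAAUAUC	158	88	121.7189527	-0.376370733	0
hvu-miR168-3p+star	GAUCCCGCCUUGCACCAAGUGAAUCCCGCCTTGCACCAAGTGAAT	404324	293248	405.2687856	0.004523768	1
hvu-miR399	UGCCAAAGGAGAUUUGCCCCG	2	1	1.383169917	-0.532021604	0
hvu-miR5049	UCCUAAAUACUUGUUGUUGGG	549	121	167.3635599	-1.713820705	0
hvu-miR397	CCGUUGAGUGCAGCGUUGAUG	8	7	9.682189416	0.275333318	0
hvu-miR166/b/c	UCGGACCAGGCUUCAUUCCCC	19883	6967	9636.544809	-1.044947586	0
hvu-miR1126	UCAACUAUGGACUACAUACGGAA	13	0	0	NUM	0
hvu-miR5052	ACCGGCUGGACGGUAGGCAUA	11	3	4.14950975	-1.406490722	0
hvu-miR168-5p	UCGCUUGGUGCAGAUCGGGAC	420777	179792	248682.8857	-0.758748623	0
hvu-miR5053	CGCAGCUGUAGUCGCCGGCGU	24	5	6.915849583	-1.795056009	0
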