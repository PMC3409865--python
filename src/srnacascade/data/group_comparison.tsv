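stream	threshold	unique_gp	unique_tg	unique_fraction	total_gp	total_tg	total_fraction	specific_gp	specific_tg	specific_fraction	common	de_gp	de_tg	de_sum	de_percent
non_chloroplast	1	958901	422195	2.271228	3575645	2585109	1.38317	865500	328794	2.632347	93401	18346	15477	33823	36.21267
non_chloroplast	4	44148	24695	1.78773	2535876	2132417	1.189203	10367	4252	2.438147	42333	13899	9897	23796	56.21147
non_chloroplast	10	16260	10123	1.606243	2382398	2050931	1.161618	859	286	3.003497	18293	6222	3431	9653	52.76882
chloroplast	1	30387	23477	1.294331	2651785	3322007	0.798248	20673	2545	8.122986	5922	1252	1348	2600	43.90409
chloroplast	4	3929	3828	1.026385	2617582	3296389	0.794076	555	181	3.066298	3518	1252	851	2103	59.77828
chloroplast	10	1442	1574	0.916137	2603761	3283687	0.792938	42	29	1.448276	1736	670	434	1104	63.59447
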