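mirna	sequence	count_gp	count_tg	normalized_printed	log2_printed	mfe	location
Hv-miRX1	GAATGACGCCGGGTCCGAAAG	25	20	27.6633983	0.1460503	-204	dbj|AK252042.1|
Hv-miRX2	AGTGACGCGCATGAATGGATT	269	183	253.120095	-0.08778413	-143.1	dbj|AK248318.1|
Hv-miRX3	TGCTCACTGCTCTATCTGTCACC	5	1	1.38316992	-1.8539497	-169.5	dbj|AK372560.1|
Hv-miRX4	AGGTGTCATCCCGCCTGAACA	2	5	6.91584958	1.78990649	-152.6	dbj|AK370571.1|
Hv-miRX5	ACTGGTTGGATCATGCTTCTC	101	39	53.9436267	-0.90483087	-113.5	dbj|AK252755.1|
Hv-miRX6	ATTTACTTGTAGAAGAAGCTA	20676	14730	20374.0929	-0.02122128	-189.9	dbj|AK357352.1|
Hv-miRX7	TCAGATGAGAAGGCAGATCATA	135	41	56.7099666	-1.2512852	-210.4	dbj|AK364228.1|
Hv-miRX8	TAGGAAAGTAGAGTAGGCACA	6	5	6.91584958	0.20494399	-58.3	gb|HQ619243.1|
Hv-miRX9	ATTGACGACCTAGATACACGTGCA	77	15	20.7475487	-1.89191755	-60.1	gb|EF012202.1|
Hv-miRX10	TCTGTAACTTAATATAAGACG	33	8	11.0653593	-1.57641572	-137.4	BU991655.1
Hv-miRX11	TATTTGCAGGTTTTAGGTCTAA	3876	1806	2498.00487	-0.63379228	-43.1	dbj|AK248748.1|
Hv-miRX12	AATTATTTAGGTACAGAGGGA	42	20	27.6633983	-0.60241093	-146.2	dbj|AK367701.1|
Hv-miRX13	AATTAATATGGATCGGAGGGA	20	13	17.9812089	-0.15350998	-114.1	dbj|AK358446.1|
Hv-miRX14	CCGAACTGATGGAAAGGGCTA	46	17	23.5138886	-0.96812072	-75.8	gb|EU282577.1|
Hv-miRX15	TTTTGGTTGCGTTGGCTAGTGCAT	9	4	5.53267967	-0.70194661	-51.8	dbj|AK366688.1|
Hv-miRX16	TATAGTAATGATGGCTAATGGT	1149	263	363.773688	-1.6592657	-97.2	dbj|AK364228.1a|
Hv-miRX17	TTAGGATTAGGAATAGGTGTA	28	12	16.598039	-0.75441402	-65.2	gb|EF115541.1|
Hv-miRX18	AAATAGAATAATGATCAACGGA	22	3	4.14950975	-2.40649072	-37.1	gb|HQ619322.1|
Hv-miRX19	TTTGAGGGTTCTAGTCTTTGC	5	4	5.53267967	0.1460503	-117.9	gb|AF521177.1|
Hv-miRX20	ATCGTATGAACTTGAAGCAACGGT	50	11	15.2148691	-1.71644617	-119.5	gb|FJ477093.1|
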