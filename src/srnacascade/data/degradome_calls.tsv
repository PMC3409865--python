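mirna	mirna_sequence	position	tag
Hvu-miRX1	GAATGACGCCGGGTCCGAAAG	10/11	AGGCGTCATTCAAATTTCTG
Hvu-miRX2	AGTGACGCGCATGAATGGATT	10/11	GCGCGTCACTGCAACGGATAA
Hvu-miRX2	AGTGACGCGCATGAATGGATT	10/11	GCGCGTCACTAATTAGATGAC
Hvu-miRX2	AGTGACGCGCATGAATGGATT	12/13	ATGCGCGTCACTAATTAGATG
Hvu-miRX2	AGTGACGCGCATGAATGGATT	13/14	CATGCGCGTCACTAATTAGAT
Hvu-miRX3	TGCTCACTGCTCTATCTGTCACC	10/11	GCAGTGAGCAGCCGGGTTAA
Hvu-miRX4	AGGTGTCATCCCGCCTGAACA	10/11	GATGACACCTTTAGAGCGGG
Hvu-miRX5	ACTGGTTGGATCATGCTTCTC	10/11	TCCAACCAGTCAGATCCAACCA
Hvu-miRX5	ACTGGTTGGATCATGCTTCTC	10/11	TCCAACCAGTCCGACGATCCAA
Hvu-miRX5	ACTGGTTGGATCATGCTTCTC	11/12	ATCCAACCAGTCCGACGATCCA
Hvu-miRX5	ACTGGTTGGATCATGCTTCTC	12/13	GATCCAACCAGTCCGACGATCC
Hvu-miRX6	ATTTACTTGTAGAAGAAGCTA	10/11	ACAAGTAAATACGACATGGG
Hvu-miRX7	TCAGATGAGAAGGCAGATCATA	10/11	TCTCATCTGAGTTTGATCCT
Hvu-miRX7	TCAGATGAGAAGGCAGATCATA	10/11	TCTCATCTGAAATATGATCCT
Hvu-miRX8	TAGGAAAGTAGAGTAGGCACA	11/12	CTACTTTCCTACAAAGTTAT
Hvu-miRX9	ATTGACGACCTAGATACACGTGCA	12/13	TAGGTCGTCAATCCTACCAT
Hvu-miRX10	TCTGTAACTTAATATAAGACG	14/15	TATTAAGTTACAGAGGGAGAG
Hvu-miRX11	TATTTGCAGGTTTTAGGTCTAA	10/11	CCTGCAAATAATATAGCATGT
Hvu-miRX11	TATTTGCAGGTTTTAGGTCTAA	10/11	CCTGCAAATACCTGGTTCTC
Hvu-miRX12	AATTATTTAGGTACAGAGGGA	10/11	CTAAATAATTTAAAAATGGA
Hvu-miRX13	AATTAATATGGATCGGAGGGA	10/11	CATATTAATTTCGACAACCC
Hvu-miRX14	CCGAACTGATGGAAAGGGCTA	10/11	ATCAGTTCGGCAGAGAGCAGA
Hvu-miRX15	TTTTGGTTGCGTTGGCTAGTGCAT	10/11	GCAACCAAAAGTCCGAACTAA
Hvu-miRX16	TATAGTAATGATGGCTAATGGT	10/11	CATTACTATACCTTCCCTATT
Hvu-miRX17	TTAGGATTAGGAATAGGTGTA	10/11	CTAATCCTAAGGATTCCTTAA
Hvu-miRX18	AAATAGAATAATGATCAACGGA	10/11	TATTCTATTTCACTATTTCA
Hvu-miRX18	AAATAGAATAATGATCAACGGA	10/11	TATTCTATTTTTGTTGGATC
Hvu-miRX19	TTTGAGGGTTCTAGTCTTTGC	10/11	GTGTAGAACCCTCAAATGAG
Hvu-miRX20	ATCGTATGAACTTGAAGCAACGGT	10/11	TTCATACGATCCAACGAGTTC
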