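name	sequence	role
ADV-1-F	AGGCCCTTTCGTCTTCAAGAATTGCGGCCGCTGAGGTGGTAATAGATACTCCAGACAAGACA	vector_adjacent_fwd
ADV-1-R	ATCGGCTCTCATCCTCGCACAGAAAGAC	internal_rev
ADV-2-F	AGGTCAGGAAGAGTCTTTCTGTGCGAGGATG	internal_fwd
ADV-2-R	AAGGCCATCCAGCCTCGCGTCGCCCGAATTCGAGGGCGCAAATGAGCAAACGG	vector_adjacent_rev
ADV-3-F	AGGCCCTTTCGTCTTCAAGAATTGCGGCCGCAAGGGGCAACCCGTTTGCTCATTT	vector_adjacent_fwd
ADV-3-R	CATTGGAATAAAGGAAACTTCGCCATAGATTGG	internal_rev
ADV-4-F	CTTCAAGCCAATCTATGGCGAAGTTTCC	internal_fwd
ADV-4-R	AAGGCCATCCAGCCTCGCGTCGCCCGATATCATATCTTGCACGCCTGCCGCACAAAG	vector_adjacent_rev
ADV-5-F	AGGCCCTTTCGTCTTCAAGAATTGCGGCCGCACGGCTTTGTGCGGCAGGC	vector_adjacent_fwd
ADV-5-R	GTTGGGAAGAGGGAAGTGAGGTGCTG	internal_rev
ADV-6-F	TTCTCCCAGCAGCACCTCACTTCCC	internal_fwd
ADV-6-R	AAGGCCATCCAGCCTCGCGTCGCCCATCGATTGCAAGTTAAGCGGATGTGACGTCCCG	vector_adjacent_rev
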