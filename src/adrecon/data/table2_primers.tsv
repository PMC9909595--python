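name	sequence	role
ADV-5-F'	CGATAAGCGGCCGCACGGCTTTGTGCGGCAGGC	subclone_fwd
ADV-5-R'	AATAGCGCCCGGGCGTTGGGAAGAGGGAAGTGAGGTGCTG	subclone_rev
ADV14forLG-F	ATCGCTCTTCGTAAAACCTCTACAAATGTGGTAGATAAATCACTTACTTAAAATCAGC	deletion_fwd
ADV14forLG-R	CGCGTGCTCTTCGTATATCTGGCCCGTACATCGGATTTACCTTCGATAGTAATCC	deletion_rev
ADV55forLG-F	ATCGCTCTTCGTAAAACCTCTACAAATGTGGTAGATAAAAATGATTAATAAAAAATCACTTAC	deletion_fwd
ADV55forLG-R	CGCGTGCTCTTCGTATATCTGGCCCGTACATCGGATTTTTTAAACCAATACCACAAC	deletion_rev
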