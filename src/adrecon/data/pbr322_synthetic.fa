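>pBR322_synthetic
TTATTTAACATTGGGGCGGCCTCAAAGGCCGTCGCAACCACTCCCAAGTCACACGTCTGGGCCCCTGGAC
TAACGAGAGGTACGCATCATTCCCCGTCGGCCGGGCGATATGACCTAAGACGGTCATACATTAGTGTTAG
CGGCCTATACGACATACCCTGGTAAGAGGCTTTGTCTTTCTTAATTGTAAATTCAATCCATCTGTCGGCA
GTTACAACCAGTCAGTGCGCCCATTGTTCACATGTAACCGCCGTAATTAAATTCGCAATCGACAGATCAA
CTTAACAAACACAGACTAAGATTGGGCCTAAGGATTAATTACCAAGCTTTGCCTTTCCGATGACAAGCTG
AAAGCCTGTGCCCAGGTCTCGCTTTGGCACTCATAACTCGTGCCGCGGGATATAGTGCTAGTGGCCCACG
GGTCAGTTCCGTGACGCACGTCTCGAAGCCGCTCGCGTTTTTCCTACTTCCCTCCACAAAACTAAAACTC
GTTGCAGTGGGCGCCAAAGCAGGATCCATTGGAGTGTCTTTCAAGAGCGCTTCAGCTCCTCAGGAATTGA
TCCTTTAAACCACCGTGGCTTTTGAAAGCGACTTGAGGGGCAACTGTGCATATAAGTACCTCATCTTGGC
CCTAAAGATTACGGACAACATTACATCAGTTGCTCCTGCCTACACTTACAGAGCGTGATGATCAGCTAGT
TCGTGGCAGCTCAGAGTCGTCCCTCAAGGACAGCGTTGAAATGTGACGCGAAACGGCAGGCAGACGGACG
CCGGTGTTATTCCGAACTACAAGCGAAAGCACTTCTGGAACCGATTCCGTATCGCCCACTGTCGAGCTTG
GGTGACGTCTCGCAAATGTTACTAATCACGGAGCTCAGCTTTTCCCGTACAAATTCAAACTTCACTCATG
ATCGCGTGACGGCATACTATGGTCATCTTGTAGATGTATCATAACGCGGAAGGCATCCTGGTTGCGACGC
GAGGCTGGATGGCCTTTGCCTCCCCGTGTGTTGTCCACCTCGGCCTAGATGGACTCCTGGGAACTAATAG
TGGCTTAGCACTTCCTCTCTGGACAGAAAAAGATCGCGGTGGTGAGTGTATATGCTAGGGGTAATTTCCA
TAGATTTGCCGAGCCTCCCATGGAGCTGGGAGCTGGCCAACTTGTGGCAAGGCTGTTGGTGTCGTTCTTC
CCCCTTTGCCGGTCGCGGGGTGTTGAGAGTTTCGGCCAAGGCGATCGTTAAGAGTTTCTGGGAGTAATTA
ATTGGAGCGTTTTCATGCAACCTCGCGTTCCCGCACATCGGCCCGAGAGAGTCGATTTGAGGTGAGAATG
TATCCTTAATACGTTAGTAAAAATATAGACAGTAATTGCTTAATCCCGTAACCGCTTTCGTTCATACTCG
GACAGCCCACTCTTGCCAGACTACGTTAATGGACCTTACCCCCCTTCTTTTCTACTCTGCTGCGCATCCA
CATTAGTTAAGATGAATTGATTTGAGCTCATCGGCGAGAGCTTACACGTGTTCACTTCACAACTTACTTA
GCCAGATGAACGGCTGTCCTGTCGTTGTCCATGATCCTGGTCTTACGATGCACGAGCGGAGGCCCGAGGA
GGTACCTGTGAGCAACTTCAGCGATTTTCCCCATTAAGGCCTCGCGAGGTTATGACCTGATAGATGCCTA
ATAGCGTGACATAAGGGTGCGACGTTCATTAGTCCAACTTATGAGCCGCATAGACAACTCCGTGCACGAC
TTCCGAAATTCGACTGGTAATGACAAGGTTTTATAGACGGTGGGTTGGCCTACTGTAGGAGTGCTCGACT
GGCTCTATAAGATCCGAAGGCAACGATGAAGACTGGAGCCGTGCTATACCCTCCTAATGCTACTGAATTA
TTGGCGGACAATTTAGGATCTCACACAACGTTTGCCGCCAAATGGTGGTTAACACGCAGGAGGGTCTGTC
CTCTTTCCTTTGGCGATGCGTTAAGGTTATCATCCGTCCGAGCAGTGTTTTGCTGTGGCATACACCGTCC
CAGAGTCAGCATGAGCTAAGAGTCAAGCACGAGCTGCCCTCTAGCCGCAGTCGCATCTAGTTATCTTCGA
ATAGTAGAGTTGGCGCCCGTGTAAGCATCTCTTGAGTGATGTCAACGCGATCATGCGCATACCGGACTCG
TTTAACGAGGTAATCCACGGCATTTGCTTCTATTTCTCAGTCCGGCCGCCTCTGGGATACTGAGTCCGGC
ATCCTGCGCTTAGAAGTGGGCATGTAATATTTTGGCGGCAGAACAGCTAGGGGCCCTCCTTCGAATGTCG
GAAACCCGCGCTAAATCACTGTGGTCCGTTGGCCGTCCCTCTGTAGGTTCATTAATCGCAGCGTACTGTT
ACAGGGGACCTACTCTCTTCGGTATAAGCGTACGCCGCTTCTATGGGGCCGGCGTCGCTGGACTCGAGAG
TTCGTGGCTTGCACGATCTTGGACGGCAGGCGCGCACAAACGAATTGTGCCGACGTTTTCGAATACGAAC
CCGATGTGTTTGAGTATCCGTTCGGCTACGGCGCGGCCGGCGACCCTATCTCTTGATCACGGGGCGGGAT
CGTTAAATGGACGTCGGATCTGTGGAAACTGTGCAGTACAGTCGTGTTCTCCGCATCTCAAAATGCGTCT
TCCTACGATAGTGTCCGGGTCGAGCAAGGAACTCGGTTAAAGGGTCAGACTACCCTAATAAGATTTGAGG
AGACAAGACCTGTACTTGCGAGGCAGGAGTCACGTGATCGGCGCCCCTGTCTTGGGGTACTCCACTAACC
TTCCAGCCCAGAGAACTGTGATCTCTCACCCGGTGGCATGCGCCTTGCGTATGGATTCTGGCTGTTTAGT
TCTTCCAGCGTTCGCAATTTAGTGGTTGAGCCACATTACTCATCCCAGGAACTTACGCCACGAGGCCTGC
GTTATAGGGACCTTCTCACGCCACTCGTGGACAAGGTGGAAATGTGGCGCGCGTCCGACGTGCACAGTGG
GAGTGGCACCCCAGCAAGGGTGCAGATATAGGTACCCGCCCCTTGTTAAAAAGCCTCCGGGAAGCAGTTC
AGCTAAAGGGCACCAAGGAGGCCGCCGAGGACTTTGCAGACACGTGTGCTGGTAATGTCCCCAGGGCGTC
AAGTTAATTCCTAATTGGGTCTATATGAACTCTCAGTAAAGGGTAAATCTCGATCGTGCTCGTGATCGTT
TTATGTGGGAGTTCACTTTAACTTGGGACAGTGGGATGACGCCTTGGAGCCTCAATATAAAATAAGGTCC
ATGGGATCTCGGGTTCCCCCGGTTGGAAGCCTGGACAAACTCAAGAGTACTACTTGCACTAGCGAACCAA
TTAACAATTGATCATGGGAGCACAATAGCCAGTAGACGGCCGACCCACTTGCACTCAATGGCCAAAAAAA
AGGGGTCATGGCTGGCCATTATACGTTCAGACAAGTCAGGCGAAGGCTTTTCTGAGTGGGTGCCGGGATA
GCGCGGGATTATTAAGACCCTATAACGCGGAATAGTTTTAGATCTATCTTAATACTGGTGCCCTTGTTTT
CTGCTTCTATGTGGCGTGTGCTGGGTACATGCTTGAGGAGCCGTATTTAACTACCAGTACCGTTGTGGGT
TTTTAGGTACCTAGAACAGGGTGCATTGCTAGAACTGGCGGTTGTATAAGTATGAGGCGAGACAGAATCA
TTATCCCCAGAGTCAGAATATATCTTGCTGCTAACACGGGAAGGTATAGGAAACGGGGATCCAACGGCCA
TTGGTGTACGTCGAGCACCCCCTGCCCGTAGTTTTCGGAAACAGCGAACTCAACGCACCACCGGGGGCAC
TAGATCATACCTAACGGTAGCCCCTCACCGAGACGGAAGTCAGCCCTGTTAAACGTTCCGCCTGGCTTTA
TTCTTAGCTCGACCACCCGTCCGGTCTCTTCGAATTTGCTCTGGCAAATACATTGAACACAGATCTAAGG
TCCAACGGGAACATTTGTGACAGGATAGGAATGGTGAGTGTCACAATTCTATCTTTGATGCTATGGCACG
TTGGTTGTGGCTACGCAGGTCCCTCATGTCTCGACCTCTAACTCCACCATATAACCCAGGATACTGAGGG
ACCTTTGAGCGTGGACCAGATGCAGCGCCGGACCCATGGCATGTGAAGTTTACAGAGAATGGGCTGGCCA
CTCAACGAAGCCCAAACCTAACCTATCCAATGAGATCAGTAACCTCCGTATCTCTGCGAGGTTTTTTGTG
CGTCTTGCGAGGGCAAATAGGGGTGTGACCCGATTGGAAGCTGTGGACACCTCGTTACACGAAATACTGT
AGGCCCTTTCGTCTTCAAGAA
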