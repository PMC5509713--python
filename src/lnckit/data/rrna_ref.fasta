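>rrnaref_00
GCCCGCAACCTATTGACCGGAGGGGCGCTCCCTTAGACTTGCAGAGACTTAAGTCAGTTCGAAGATACCC
ACACGGGGCACAAGCAGGTTAATAGATCTGTGCCGCGAGTGTGCACGAACACCCGGTACGGGCCGTTGGT
ACCGCAGTAATACTTATATACCTTATTACTGCTTCGCTCCTGATATGCCTTTTAGTCAATTATAATTACG
TTTTTTAAAGCCGCGTTTACGTCAGGGGAGAACACAAGACTGAGCGATTAGATTTACACTCGTGAGGGGG
CAATCGGGCCCAGAACGGTCTCGATTGACTGGATGTTATTTAACAACTATTGGTGGAGACTGACCGTATA
CTGCCACTCCTGACCTCGGTGCGAGCGACACCTACTCCCTTCCTGTCAACTCTCCACTTTTACCGTCATC
CGCATGGACTCCCTCCCTGTAGCATTATCAAGGTAGCGATCCGCCGCCATATATCGTTAACCACAGGGTA
GGTATTATAGAACGTGCATCGCAGTCGCCTCGGTCTGTAACGAAGGGGAAGACGCAGATGCAACATTGAA
ATAGGGGATCGTTTCCTCCCGCAAGATTTTCAGGCTATTAGACCAAGTCGACGACAGTGATTAACCCCGT
GCTCTATACCTCTTTAGTCAGTAGCTCGCACACCCAGACGTTCACATATCGAATAAGCCCGGGCATTCGA
TCCAATGCCTCCGCCCGTTAGTATGGGGCCGGATGTGTCGGATCGAGGCTGGACTCTCGAGTTCCGCCCG
CTTCCATATTACGCAATGCAACCCGGTGGC
>rrnaref_01
TTATCCGAGGCGACCGGATCAAATATAGGAATGCCACGCTCGATCGACCTCGACAGTAGAGGCACACATT
TACGGACCTGTGACTTTAAGATTATTACGAGCGGTAGTTGCCTAATGTAAATCGGTTCCCAAACTTCATA
TCAATCTCGTGGGGTGACAGCTCCACAGGTTGTGTGGCGCGGGGAGACTCTCCAAATCATCTTCTTGTGT
ACCAGTAAACATCACTAATGTCCTGTGATGGCTCTACAGTCACTAATTTACAATGTAGTCTGAATGTATA
TATGCCAATTTATGACCGGATCCCTGAGTCCCCACCTTAGAGGCGCACTGAGAACACGTTGTCACTGACG
GAGCACGTGAGCCCAGAAAGTAGTTGGGTGCGGCCCTCCACACATTTGGTCTGTGGCCCATACCTGTTCC
TCGTTCACAGACCTACTCGTTCTACTCAGAGATAAGTGAATACTTCTTGTTACAGAGAGACAACTGGCTC
GGAACGTACTAAGGGCGATGGGCTATGCTAACACGTATTGTAGCTCATCTCGACTCCACGGAGGGGCGTT
TTTGCGGAGCTGCCTTTGAGTAAGGCTGCTCGGCCTACAATCTGGAAGACATAACTGTTTGAGAGCGATA
TCAAGAAGCTGCAGAAACAAGCCGCTCCTGTCTAATGACCGGTTCGTGAAGCTTGACCCTGTTAATCAGT
CGACTATATTTTGAGGGATCGGTCGCGTCCTCGGCACATACTCAAACCGACACTGCAGAAAGACAGCGAA
TGCGTAACCAAAACAAACGTGACAGGACCG
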