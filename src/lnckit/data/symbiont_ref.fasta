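>symref_00
GAGTTTCCATCCCGTCAGCAAGGACAGTTTGTTTGACACCGAGCTTGACCTTGGACCTTAAAGGCTCTGC
GTGGTAGATCTAAGTGAACGGTCTTGCCCGGGGTAGGCAGAAACGGGACCAACTGACTAAGTGACGATGC
ACCGCGTACGGGCTATGACGGAAAGCCTTACTTAGGGCATTCGGCGTACCGTGTGACTTCGTAAACGTTA
CGGCGTAAGTCACGACCCGTATTAGTCACGGACAGCGGTGCTGTCGAAATTGGCGGAAAACAGAGGCACC
TTCCGAAAAGCGCCCCTCACTTCGTAGTTGTCGGATTTAGCTCCAGAACAGGGCTCCCCCTCAAAAAGGT
TGGCCACGATAGGATAAATTCCCGCTAGCTGACTGGAAAGCTCACGGGGGCCTACCCAATATGTACGTAC
ACAGAATCACACGACGTGAGCTAGCCGACGTGGGTTACCTGCCGCGAAGAATCGGCAGGCTCGTGCAGTC
AGTACTGCTATGGAGGAAGCTGAAAGAGCAGTTGATATTGATCGAGGTTGAGCCTACCTTTTTTCCTTCA
GCGAAAGCATAAACGATGAGCGTCGTCCCCCGACTTATAACTGCATTGTGAGTTTAATAGAGCACCGTTG
AACCGAAGGGTCCATACGTGAGGCTCAGATCGCTCGCTGTGGCTATGAGCGAGGATAAGAGCGTTAGCAA
AGCACATGGAGCTTGGTTGATTTCCTTACCCGCACAATGCGTAGAGTGCATCGTCTCTTCTCTTCGTTCA
CTGCGTACCCCTTGTCTAAGGATGCTAACATTGCAACCTCCTCATAACGGAACTAAAGCTATAGAAAAGG
TGACTCGATCCGCGGCAGTTCACATAACCCCACGAGAACACCACTGCGTCTCCAGAGCTTTAGACTGATA
CTAGGGAATAAAAATATGGAGTACTCAGTATCCCCATATACGGTCATCACGTGATAGATCCCACGCTGTG
CGATCAAGTAACAGTGTAAGAGGGAAAATGGGCGACCCCTGACAGCTTATCTAATCATGTCTTATGTTG
>symref_01
TAAACAGGCATCATATGGATTCCGAAATATAGCCATCCATTCCCCTTCGATAACTATCCTCGATTTATTG
ACGTCCAGGAGGCATGTTAAAGGCAGCACCGTGCCCATGACTCTTTACGACGAATGAGGAAAAGAAGTTA
GCTCAAGCAGACTGAATGCAGCGCCAAAGGATTGGCCATTAACGGACGGCGTGCATTAGCCTAACAGCCT
GGAGCGACGTTTGCGTCCCTTATACCTCGAGAACGGCGGAGCTGCCTGGAGGAAAACTAGATGGTTTCTA
GCGCAGTGTGGAGAGATTATTTCCGTCGGTAACGTGATCCCTATCATTAAGCAGATCCCAGCTCCAACGT
GCGTGCCTATCCCCCCAATGAGTTGTTGCCTCTCGCTACGCTACTGGCCTCATCTTTATCGATATTTCTC
GTATTCAGTTTCGATCCCACAACGGATATAGCTATTCCTGACGTTGATTACTGCCTCATCTCCGCGTGTA
TTACTTCACCGGCGGGCTTCGGCAACGGCAGTTCGTACAGTACAATATCTGAGTATACCGGCAGTACGGT
GCGCAGGGTTAAATGATAGACGGGCGATAGCGGTGTGCATAGCCATGTTCTTTCCGCCGGGTACGATTCG
TGTAAGGGAGTGCATCTCAACGACCCTAAGAAATTCCAAGCCCCTGCAAACCGGTCTGAGCGACACTCGG
TTATCTATACCATAAAGCCTCGGCGCGGCCTTTTGCTTTATAATTTTCGTCGCTTTAATTAGGCCGTGGA
CGGCTACTAGACGACGTACGTGTCTCTGAGCGTTGATGCGC
>symref_02
GACGTATTCCTCTCTGGTTTCCAGACTTCGGCAGCATCTATACCTCCCTTCCGGACACCCGCCTGCGTCC
CCGGGAGATGTCCTAGCCCAGACCCATTTACATCGGTACCTATTACCTATGATAAGAAGGATCACGGCGG
GACTACCAGTGTGAACAAGGGTGTCCGACACCGCATTTGCAGTCGGCTCAACCGGGGGATCGGGTAGGAA
GAAAGCCGAAGCGTTCACCGTCAGGGTTATGCGCGAAGGCGGTTAATATTGACGGCTGCTCTCTCTGGTA
CCTGCTGATACAGTCCTGTTGTAAAGGCTGATTTCGCCAAAGAGCCATAGCAATTATATTGAATTAGGAA
GTTTGTATGGGCAGCCCTTCGTTATGACCTATGTGGTATCGCTGAAGCTGAACCCCTCAGTTAATGGTCA
GGCTCTAAACTCCACTCAAAGCCGAGTTCAGTCTTTACCGTCCATCTAGGCCCATCTCTCATCGACGTTG
TCAGCCCAGGGCGATGCTGAAAATAGCTAGAGAACGGTCGTTTAACTCGTTATAGCTCCGAGATTCAATC
TCGAGTAGTGGAGAAATTGCAGTTGACCATATACTAGTTAGCAATTATGTTGTCGGCAGCGTGCGGAAGT
CTTATTTTGCACCTACCGTATGTCTGTGGTGGATATCTTCTAGTCGCACGATTGCAATGTCTGCTTGCTC
GCGGTCTACCTGTTTCGGTTACAGATTACCATCACTCCCTACGGCACTTCGTGTAACACGGTCCGCTGAC
TTCCAAAGAGTTAGTGCCCCTGAGGCAGATAGTTCGGTTGGGTGTGTTATCTCTGCACGGGCGGGCTAAC
TTGTCCACAACTGTGGTATAATATCATGAATTGAGAACAAAGAAGCTCTAAGGCCTAATAGAAACCCGTG
GAAGCCCCGCGGATCGGTCCTAACTAACCGAGTGCTACGATCGTGAGATGACACATGGAGTTGCGCGAGG
ACTCCCAAGTGCGTGTCGTTAAGCTCTTACGAACGGGCGTTGCTTTGACGTCGGTTACCCC
>symref_03
TTATTAATAAGATACCATAGGGTCTTGGCTGCAATATGTAAAATGATGGGGCTATGTATCGGGACGATTT
TGCACGTAAGGGAACCTAAATCGAAAGTCGTTTCGCGCAGGGACACTGCAGTGCATAATTGACGGGAATG
CGTACTACTTGCTAAGTTTAGTCTTTTGATAAAGTCTCACGATTGAATATCCTCGCCCTAAATCTCCTAG
AACATTGTGTCGGAGAGTAAGCATCGTTCGTCACGCAATTAGGTATAAGAGATTGAGCGGGGCTCGAGGG
AGTATGTGTCGCGTCGTGGATCTGGTCGCTAAATGAGACACCCCGCTGTACGCGAACAACTCAGGGGCGG
GTACTTGGTATATCACCCCCGCAATAGGTGTGATGGCGATTGGTACACATTGATTCGAGAACATTTGACT
GTATCCTGTCCAGTGAGTGGAGAGTGCGTCTTTTGTCGTCCACACTCCGGATGTCGCGTGATGGATGGCC
CTGATTTGTTTTACATTTAATGCTAGTGACATGTACACAATCCGGATAATTCGCATGACGTTTAGACTTG
TTTGGCCTGACGTCGATATCTTGCATCTTAGGGCCACAACCTATTTTCAGGGCAAAATACTAAGTGTGGC
CCTTGGCAGTGCAAGGTTGGGTCAATTCTAGCACATCCGCTCGAGGGATGCGGAACATCCCTAAAGCATT
TCAAGTCACTGAAAGCGGCACAGTACTGTCGCCCAAATTCAGTCGGTAGGTACTGTCCAGGAATATATTG
TGCGACGCCCTCCTTGGATTCATATTCCGCTGCTACACATCCATATCACGCAGGTCATAAGGACCTTAGG
GAAGTCTATGGCCACGGATGGTTTGTAGTACTTGAACACATCTGGTAATGATAGCGTACGAGAGTTCAGC
CCAGATTGCGAAGCTCTGTAGATAAGTCGGCCTTTGAGGAACCTCTCTCCAGGCAACCAGACTTAGCTAA
CGATCCCATCCAGAGTTATGTCCCAATGTCGCCTCTGCTTCAAATAAAACCGGGGAAGCAAACCGAGTCG
GCGAGGGCATGTACTTTCCGAACCTCGCGAGCTTGGGGATGGAGCATTCAATCGCTGAGAGGTAATTGCC
TAACGGTCGCATTAGAGAAGGGGTAGGATGATGCGTAACCGTGTCCTGGCTCAAACATAACCAGATTTTT
CATAAGAAATACCCTCCAACAGACGGTCAACGGGCTCACTGATGGCGGTCTCAGTCTATATAA
>symref_04
GCAACTGATAGGTTTAGTGCGCAGACTGATGAATCACGTGTCTATCGCGATGGACGGAGAGACTCAGACA
CAATATAACCCATCTTGAGGCCCCAAGCGGGCTAGCGTTTTACACGCCTGAAAACAAGTGGCTCCGCAAC
ATACTGATTAAGCAGCTCTACGCGTTCTTAACGATCGCGTCAGATCGTCGTAATGAGAAATCCGGGCTTA
CCCGCACGTATCAACTGCAGCGGGCGTCAGCCCCGACGGTTGCGCTCCGTGCAATGTTAATTCTAGAGAC
GTCATCGCAACTTGAGGGGTCATGCGCCAGTCAAAAAAGGGTAGATTGGTAAGCTGTGACACTTAAGTGC
CGCGACGGTCATACTTCCTCCTTTACGTGATATTTCGCGCTCCCTAAGGTTATGGAACCAAAGTACAAGG
CGCGGTATCTTGTTACTATCCCGGTGGCACATTCGCAAATAGAATGAAAGTAGCAGTTCTGTCGCGCCGG
AAGGAGCCGGTACTCCATGCCTAAAATCCCAGATATGCATATCTTTCGGCGTCTGCTTGGGGACCGTGAT
CACCGGCACACGGTATTGTATTGCGCTCGTACCCTGTTTGCATGGACAGTTGTGGCAACGTATTCCCAAA
TCGTAGTGTTGTAAGCCCGAGGTATCCCCTTGTAGGGTCACATAGAGAACGGGCAAGATTGCCATTGCGG
CCAGCTTTCCACGAAGTAAGACGATGCACGAAGCTCGCCACCCGGTATAATCATAACTGCGTTAGCGATA
AACTTAGGAGAGCAGTGTGATACGTCCTTCTGAAAGCACGTTAGCCTATGTCAACACAACCTTCCATTGC
GGTGTCGGAACTGCGGATTGCGACTGTCGGGCAC
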