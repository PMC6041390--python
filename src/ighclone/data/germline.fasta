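>V1-26
GGTGGAGCCTGTTCATATCCGTGCGGTAACTCGAGGCTTTTGAGTCGCTTCATTTCTACC
CGCAGTTCGCTTCACGTACACTCACTAGACGCGGAAGGCGCAGACGTCATCCAACTTGGG
TTTGCAATACAATATCTAGTGCAACACCTGCAGCGAGAGAGTTTATCGAACGTACGTACC
GCGCGAGGCGTCAAGGAGATTACCATGAGGAATCTGGTCCGATGTATAGGCTACAGGGTT
TGCAAGACCCACAGTCCATCATTGCTAATCCCGCTGTGTCAATTCTGCGACTGT
>V1-7
TCACGGCGCATAGTTCCCATGCCGCTATCTAAAATCACGCTCCAACACCCAGCTAGTACT
ACCGGAACCTCATTTAACCCTTCCAAACGCGCTACGACGAAGCTTACCCAGCAAATATAT
CCGTTAACGCAAACGGAGGATGCAACAAGGCACTCCAAAACTGATGGCATTTACGAACAC
GCAGTGCGGCCTACAGGCCTTCACATAACTATTTCAACCTCGTATTCTGTGGCCTCGCCT
CGCACGCTTTGGTTACTTGACTGGTCCGTGCGGGTCCCTAGACCGTTCGTATGT
>V1-81
AGTTGTCATTCACGGTATCTGGGCTTCCTGAAACTACTTTTTTATGGGCGGTGCACCGTG
CAACGCTCAGATGAATACGGTGTCGTAAGGATACAAGAGGCGCAGCACGTAGTGTGCCAG
ACTCCATCCGGTTTTGGGCTGCCGATTCCGAATGGAACTTATCTTCATAATGCAGGTTTG
CAAGTCGCGGGTTGTGGACCATGCTGGCTTGACGGCTGCCCGCGGAAAATAAGCACGATC
TGGGGCGACATGTACGCCTCCTCCTTAGGTGGTGTAATGCACAACATTTTGTGT
>V1-82
GTACTGACGTACTACCTCGTATCACGTTCTGGTATAATTAGGGGACTTGGGCTTAATCAC
GAATCTTCGTACCATCTTTCGATATTGTATGGTGGATCGAATTGGGGCAACTTTGACGTT
TGTGCCTATCCGATGCTTGGACAAAGCATGGTGGCCGACTCACAGCGAGCCCAAGTATCA
ACGCTAACAAGCCTACCAGTGAGCTTTAACTCGCCGCGGTCACTTTTCTCAGCGCTGGAA
CGGCGGTGCGGTCATCGCTCTGTGCCCCTGGAGCGATTTGACATTAGATGCTGT
>V1-9
ACTGAATTCCCCAGACGCTACTCTTTACCGGCTGATGATTTTCGGGGAACTACGAACCGG
ACACAAAAGCACATAGATAAGGCAGCTACCAGCTCGTGCCATGGGTCTGGACTGGACCAT
GCATGTCTGTGCTCTCGTGCATGTGGCATGGGTACTCTGTCGATGATTGCGATGGCCCCT
CCGACGATACTGGGACAGTTAGGCACGTCGAAAGTTGTATGTTTGTGCCCGAGAGTGCAC
ACGGTAACCGATAGAAAAACTGTGACCTTGATTTCCATACGTATCGTGCCGTGT
>V2-2
CTACGCGCTTCTGATGAAAAGGAACTGAGGGGTTCAACTGACGGAAAGATCCACGAGCGC
CATCTGCTCAATCCGCGGCTGATAATACTGAAGAGGACCAACAGCCCCCTAACAATGGCC
GGGTGCCTTTCCAATCATCTGATCCTTTGCCAGGGACGAGGACAAAAAAAGCCGCGGGGA
ATATTCCAGGGGGGCCTCCGTCCCCATGTCCTAGAGGTTGTACCACAAAAGTTATGGGTT
GGTGCCCCAGACCTGCTCGACCGGGAGACTACCACGATGACTCTCCGCAAATGT
>V5-17
GGTTCGGTTTGCTTACTCGCTGTATTGCCCTCACTCAAAGTGATCGGGGGGGTTCTCGTC
ACCCCCTTTGGTAGCAATAAAGGCTGCAGTTCTATAACCGACTTACAAACGTTTTTTTCC
TACTCGGCTGCAAAGCAGCGTCCGTCGGCAGGGCCGGGCTACTATCAGGCCCGGCCAGGC
GCTACGCTTGACGCAGTAGATGGGGTTAGCTGGAGCATACCGCCATCGCGGACTCAAGCT
AACAAGAGACCCCGCCGAAGGGGATTGCCACAGATACAGTTGTTCCCATGCTGT
>V5-9-1
ACCAAAGGTCCGAGATGTGAGTTGCCATTGTTTTCGCAAATTTTCGCACTAGACCCGGTT
TACCCACCCTCTATCTTCCCAGGTTGCATCGCATCGTATGCCACGGACGGTGCTCCATCG
CTTCTAGACCGCGTTGCTGTATTGGTTTCCGTTCCGCCGACGCCACGTCCCTCGGCCGAT
TCCGAACCAGTGGCGAGCGACGCCAATCAATGCTTGTGCACTGAACTGCTGGTTGTCCTG
GCTGAGCCCGGTGTTTCCTCAATCGGGAAGGCGAGGGGGCATGTACTACAGTGT
>V7-3
CCAAACTCCTGGGCTTTACACGGACCGACGAGGTTTAGTCCTACTTTACTTGGGCGGATG
CCGCATCCGGGGTTTTCGGAAGCTAACGATGGATTGACAGTGCAAAAGTTTCCGCCTCAG
TTCATGGTACCCAGGGGCACTGGATCACACTATACAGCGGCGAAATTTCAGAGGAACTGT
AACGGTTCACGAAGTATATTGGACTTGGAGATCCAAGGCGTGGCGCCAAACCCTTACATA
CCTTCGCCGAACAGGTCCCAAAGATGTTATCGGCTGATTGACAACGCCAAGTGT
>V9-4
ATTCGGGTGCTCAGCAAGCTGTTCATCTCACTCAACCTCCTACAGGCCTATGTTCTCACG
CCGGATGGCCTCCGGTTAGATATCCCGCCCGCAGGAGGTAGTAGTTATTGGCCTATTGAT
CCGCATCACACGAAAGTTCTGGTTGTGGCCATTCCGCTAATTAATACGCCGGCTTATTTC
AAGTATCGGGATATCTTAGGGCCAGTCATGCGATACTCGTCGGCCGGGTCCGCATACTTA
CGTTACAGAGTTAGCCTAAACATTCCCTTAGCTATTGTTCGATGTCTGACATGT
>J1
TACTGGTACTTCGATGTGTGGGGAGCTGGAACTACTGTGACTGTGAGCAGC
>J2
TACTTCGATTACTGGGGACAGGGAACTACTCTGACTGTGAGCAGC
>J3
TGGTTCGCTTACTGGGGACAGGGAACTCTGGTGACTGTGAGCGCT
>J4
TACTACGCTATGGATTACTGGGGACAGGGAACTAGCGTGACTGTGAGCAGC
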