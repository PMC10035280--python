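>SYNREF16S synthetic 1542-nt 16S rRNA reference (stand-in; supply a real J01859.1 FASTA via config for genuine E. coli framing)
GCGCCGTGGCAGACTGGACAGCAGATCCCGAAAACCCAGGCGTAGGCAGGTACCCGCTTGTGCGGCTTGGTTACCGCGAC
CTAAATATCGTCTGTAGACCTGTGGCGTGTTTCAACAGGTACTACGCAACTCGGGAAGTCGTATGCACAATACTCAAGGG
GCAAGCATCATTCACCCGATGAGCTATCAGCGTTGTTTGCAGGACAGATTATTTCGGTCCCATAGCTTAGGGGCATATAC
AATTAAAAAGCACGTAATGAGGTTGCCCTCCCGTGGACGAGGGGCTCAATGCGTTTGACCCACTGTCCCTACACAGGAAA
CCCTGGGCTCTGATTTGTCGCCATGTTTCGTCTCTTATAAGTTAGATCGGTCCTCAGGACCACCTGGCGTTGTGAGCCTA
CTCCCTCCGTTCTAGGGACCAATGTATTTGGAAGCCCGGCTTTTGTTTGGCAGGTTCTATAACCGGAAGGCACAGTGCCG
CAAATACTTAGAGGATGTCAAAAGGGCCAACGGCCGTACTAGCGAGGGTCTGAGAGTGGCGGCGCCTTGGGACCCCAGAG
CGCATGACATAGTTGCCCCGGTCACTAATAGCCGTTCCACGACGCTGAGATGTTTTCGAGTCGAGCGGCCTGGCATTCCC
GGGGCCGAGACGCCAGATTAATCCTCTGTACGCCCCGGCCTAGCCGTTAGGCTGCTCCTTCAACGCGCCGGCGAACATGG
CGTAGGACAGGCGGCGTATGTTCACTTGCGCTGCGTTGCCAATATTAGTGAACTGGGTCGCTGCAACAATCGCCCGGGTA
GTACTATGCATTAAGCAGCGGATCGAACCAGATTCACAGTCAGGGGATCCCCGAGCTGCTACGCCAGGGTTGGTCACCCC
AGTTCAATAACACAGATTCAACGTCAAGGCTGTGATCCTGGAATTTCGGATGAATTTTCGGTTAACCACACGACACAAGG
TAAACCGCCAAAGGGTAACGATCTTCGCGGGAATAGGCCCTAACCACTATCTTTCGGGGCTTTTTACAGAAATGACACTG
ACCGAGGCCCAAAGGGGAAGGGCAGAAGGTGGCCACACTGTAGGGCGGTTTTAGATTGATTTTGTCTCCTATCTGAAAAA
GAGTGCCACATTTTGTCAGCCACTCGTCCGTCAGCGCTCGGGTGGCGCTACTGCTTCCGCAGTATCCCTCGGCAAATAGG
CTCGCAGTACGGATTTCGCGCGTCATCATTCGCTTGTGCAGGTGAGCGGCAGCGGGGGCATCATCTTACGGTTCGCCCCT
TCCAACTACTGTGCCGAAGGAACTCCGGAGGGGAGTCTCAAAGGCTTAATGATTAATTGCCCACCGGGGATTCCATTGAT
TGAGCCCAAATCCGGCTCGGCCAAACCAACACTGACCCCCCGTGGCCCAGTCGAAAAATAAGCCGCTAATCACTTGGGGC
AAAACTAACGCGGAACGTCGCCAGTTAAAACTTGGGAAATTAATTTGCGCTTAGTATTCAGGGTCTGTGGCCGGCCCCCT
TTGCTAGTACAGCCGGGTACGG
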