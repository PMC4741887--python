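>KLF5_UTR_SYNTHETIC synthetic stand-in 3'UTR; miR-375 7mer-A1 site planted at nt 482-488
AGCATCTCCAGCTACTTCTCATATGAATCAAAGTTACAGCTAAATTTAGTCACATCGTGCGATTATCGCA
AACTGTGGCCCGATAAGACCAAGTAGCGGAATATCTTTCGCGAACCTAAATACCGCCCAACGATAGTTGA
TTCACCGTATCTTTGGGACGGTCTAATCCCTAAATAAGCTCGCACACGGTACCGAGGCGTTGAATTCGCG
CGACTCTCGCCTCTGATTGACGTACATGCCGCAGGAGGCTCTTTTTATCTCTAAATTCACGGGTTCTATT
CGTTGCACCGTCGATCTAAATTCGGGAAAACCAACGGGCCGATGACTACTGAGTGGACATGGGTGATGCG
TTACCGTTGTAATTGGGGATGACAAGCAGATGGGTATAGATATGAATGTTCGGGTTTGGTCCCGATAGAG
CGGTCGTTTTGCCAAGGCAAGATTTGTGTATCCTATCAGGTGATACATGCGTTGGTCGCTTGAACAAATT
CGTCCTGCAATTGAAGCGGACGCAAGCTTTAGTTCAGAATGAGATTTAGTGTTTCTGGGGATACAGCAGG
CGGGGGCACCCTTTCTCGAGCGGGACGTTCACCTGCCTTC
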