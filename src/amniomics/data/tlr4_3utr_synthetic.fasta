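>TLR4_3UTR_synthetic synthetic 2223-nt stand-in for the TLR4 3'UTR (NM_138554 length) with one planted let-7a 8mer site at 400 and one miR-125b 7mer-m8 site at 1500; not the genomic sequence
ACGTTGTATACGACGGCGGCGCAGGGGATTTCGCTTCTGCCCTAAAAACTCTGGTAACCTCATCCCCAGC
ATGGGATCACCCTGCAAACGTCCTGGTAACTAGGACCCCCCGGCGTTATGAGCAATCCGCCTCTCTACAT
AATTCAGACAGCGGTCATCCTCAAGCCCGATGCCCGAAACCGGAAGTCTGGACAGCGAGAATTGTAGGCT
CGGTGTCGAACTCTGCTGTTCAACAATTGAACGATATCAGGTCCACGCAGTCCCTCCTTTACTGGCGTGG
AGTAAATGCCACCCTCGCAGACGACGGATCACCTTTTGACGATCGCGGAGGCAGGCTCAGAGGTCATCTG
CCTGCGCATGTTCAAGGCCGCCATTAATCTTATGCGCCCCCTAGGAGTTCCTACCTCACTCGAGAGGGGC
GGGACCGCAGCCTGCAACTCTTAAGCATTGCTTTGGTTCCCACTCGAGGGTGACCTACGCGATCTTAATA
CGGGAATTACAGAATTAAACTATGGTTGGCTCACGGCCCGTGTGTTCACCTGAAGTAAGTCGTTGAGCTA
CCGGTCTGTCGGGTTCATTATTTCCGGGTAACTATCATGTATTCGCGGATCAATCCATGAGCCTCGGACA
CGTTCCTAAGACAACGATATAGGATAGCACCCGTGCTACCAGGAAATGGTATGATTTAAATTTACTTATG
GAACTTATTTATGCCAGTCGCGTACTTCTCAAAACTTCCGATAACGCTGTTCTGTTTCTGAAATTCCAAA
ACACAGCTTCCAACAGGCGTCAGTTGTCGGTGTAGCGGCAAATTTAAACAAGTCCCTTCGCATATTTATT
GAACGGAGAGGCTGCTTGAAGACCGCCGTTTGGACATGGGAGGAGTGGTAGACGAAGTGTTCCGGCTACA
TTGCGTGAGATCAAGGTGTACGGCTATGAATGGAACAAACATTAAGAAATATCCACAGAAAGCCCGGGGC
GGGTATACAGCGCCAGGAGTTTAAACAAAACGAATAATTCATACTTAATCTCACGATGTCCTATTTTGCC
GTCACCGCGCGTACTAGTACACAGTGCACTGCACGCAGTGTATAAAAGACGGGAGATTTGGGGCAGACAA
CATATCTTTTTCCTTTAACAAGTAGGGAATTTATTTTGGCACAGCACGATTCGGAGCTAGGCACATTCGG
CTTTGGTCTATAGCTTTAAAGCATGACTCGCCAACGCAGGGGACTGTAACAAGTGGCAATCACATTGCTC
TTACTGGCTAGATGGCAGACCCGAATTATTTTCATCGCTTATCGGTAACCGTGCACTTTCTTTATCATGA
TCTGTAGCCGTACGAGAGATGCGATACTGTACCCGCGCCGAGGCATGTCTGCGGATAAGGAGTACTTAGA
TCGGCCAACGTGGCCAACCCCCTTCTCCTCCCAGTCTCACACGGGTAGATCTCGTTTATTACCTTCTACA
GCTTCATCAGGAAATCGAATTTTAACGCTACTCAGGGTATGATCAACAATTCGACTTCCAACACGGTCCC
AAATTGATATAACAGTGAGGAACTCAGCCCATGATCTGAACTGTGAGGGCTGATGCACCTGCTGCACAGC
TTATTCTGAACATGAGCAGTAGCCTCAGACACAAAAGTGATGAAAGTCACTAGGCTAGGGTATCTAGCAG
CTAGCATTCCGCGTGACGACCCAGCTACCCGTGGCACTTAGTCGATGTATGAAACCCCATCCACACCCTG
GATATGTGCCTTAACGGTTTACTGCGCTAGTGGCAAACGCGAACGCCAGATATTGAACCGGCCACTTGAG
AGTCAACGGTCCCCATCTGGATTCCTCGGGTCTGTCCAAAAACACGTGCTTAGGGGTTAGGAAACACTCT
CAAATCTGGGCTAGAACCGCACCTAGCACATTAGACCATCCATAAAAACGCAATCTCAAGATTGTTGAAA
CGGCCTCGCCCAGTATAACTCCCCTCTACAAGCTGCGTGGTTTAGTTAAGTGTTGTAACTCTGAAACACA
ATGCTATCGTTTTAACGATCTGGTAGGGGGCCTATTACTCGTGTCTGGGAGTCCCTCGTGTGCTGAGAGA
TCTATCGCCTACCTACAGCCCAAGATGCCTAGAAATAGCCGCCCACCTGCCCGTAGGGGGCCTAGGAGAT
AAAGTTTTGCGTCACGGCTTTCGGATCCGGCGATGTCTCTCTACCTGATATCT
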