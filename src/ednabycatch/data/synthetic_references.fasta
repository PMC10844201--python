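>herring_amplicon_synthetic species=Clupea_harengus genus=Clupea family=Clupeidae
ACGTGTTTGGAACCGCGGTTCGCCACCCCGATTGGGCATCTCATCGATACGTAGGAAAAT
CCACGATAAGATGATAGTTTCCCGCCTAGTGTTCGCCTTTAACTACATGGTTGCGGTTGT
GATATACCCCCAGTGCACATATTTGATTACCAGTTCACGTGTGCCGTCTACCATTTAACT
CTGAGGCGCGATGGGCCAGTTCTGTCACATACCCTCAGCGACTCCCTCCAAGGTCGGTCC
TGTGAAGGCCCTGCAACCTAACATCAATGATAATCGGCTTGGCCGGATACTCGAATGCAA
CTAGGAGATCTCCGTAACACTGTTCCTCTGAATCGTTATTGCTGACTTCGGAGTTGAACT
>sprat_amplicon_synthetic species=Sprattus_sprattus genus=Sprattus family=Clupeidae
ACATGTTTGCAACCCCTGATCGCCACCGCGCTTGGGCATGTCATCGATACGTAGGAACAT
CAACGATAAGATGATTGTTTACCGCCTAATGTTCGCCCATAACTACTTGGTTGCGGTTGT
CATATACCCCCAATTCACATATTTGATTACCAGTCGACGTGTGCCGTCTACCATTTAACT
CTGAGGCGCTATGTGACAGTACTGTCACTTACCCTTAGCGAGTACCTCCAAGCTCGGTCC
TGCGAATGCCATGCAACCTAACCTCAATAATACCCGGCTTGGCCGGATACTCGAATGCAA
CTAGGAGATCTCCGAAACACTGGTCCTCTGAATTGTTAATGCTGACTTTGAAGTTGAACT
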