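>Sco|synthetic
ATTCCGTTGGAAACGGTATATTTAGGATAAATAGTATTTCAGGATGAAATACTCAGCTCC
TGAAAGGAGCTATGGTAGGGACTACCTTTCAACATCGTAGATGTCGTTTTATTCTGAAAG
AATAATGAACAAAATAGTATATTTTGGTAA
>SCP1|synthetic
AGGATGATATCACCTTACGGAGTAAGATGAGCTTAATGAAATTAAGTCATAGGCTACGGA
ACGTAGCCGTCTACAGGAACTGTAGTTATTCGGAGCGGAGCTCCGAATAATTATTCGGTA
CGAATAGATTTCTAAAGTATTTAGAATCTT
>Sg13350|synthetic
GCAACATCGTCTGTAAGACGAAGTCTATCGGAGATAGATCTATTGGGACAATAGCCGGCT
CGACGAAGTCGAGTGGCGGCATGTAATGCCGTATTAAACCGGAACGGTTTATTCGACAGG
ATGTCGAATTAAAACGGTGAAACCGTTTTG
>Sg2247|synthetic
ATTTCAACCCTTCTATGTAATAGAAGCGAGCATGGGGACCATGCAGTTAGAGAATCTAAA
AGCCTCGGAGAGGCTTGGTATTGTAAATACCATTTATATATCCGTAGGATATAGCCACCG
TCAGAATGACGGGGACAAAGAATTTGTGCG
>pRL1|synthetic
GTATCTTGCAATATAAGGTACTTATATATTTTAAGTGCAGGATGCACTTAACATAGCTTG
GGTACCAAGCTGGGATCAGGGAACCTGATAATCCGTGTGAAACACGGACACAAAGGGGAC
CTTTGCTAAATGACGGGAACCGTCAATCTC
>pRL2|synthetic
ACTTACTATTCCTAACGAAGTTAGGATCTAGTCGGAGACTACTTCTCGGGTGAAACCCGA
TATGCCGGGGACCGGCTCATCGTTTGAAAAACGATACGTATAGTATATACTACGTTAACG
TAGTTAACAATTATACCCCGAAGGGGTAAG
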