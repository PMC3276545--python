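>synthetic_venus_cds synthetic stand-in for a Venus-type YFP CDS; 717 nt, 35.56% GC, constructed, not a natural sequence
ATGGAATGGATCGTATTTCATTTACAGGTCATTAACTATATTTTTAAAAACACCGATTAC
TTGAGTAAATTCGATCACAAATTCAGCAAACAGGAACCCAACCGGATCATAAAAAATAAG
CGCAGGTCGATCATTGCATTTTATCCTAATTATAGCTACAAATGGTATATTATGATACTG
AGCTATATAGTCAGTAAATCCTTCAAGATAATTATCAGTAGCTCCAATATAACCTTCTCG
ACCTTGACTTACAATTTCGTCCCGTATAACGAAATCAAGGTTCAGAAGTATGGGATCCCC
TACCCTTTTAAGCTGAATACGGAAATGAAGCATTACCTACGCGTTGTTTTATTCGAGTTT
TATTTCTTCTTTTTCTCTAATATAGTATTCTATCGCGACACCACGTTACTGCTTAAAAAT
GAACATCGAACTTTACAGTACAGCATGCTAAATTGCTTAAAATTTATTCAAAAGATCAAG
TGTGTGGTGCTAGTGAAGTTATATATTCATCTACTATGTTCATATGCTCTCATCCTCCTT
AAATCCTTATACTGGCGATACAAAGACTGTATTGAGAAACTATGTAGTAGCGTCCTCATC
CACCTTCTCCAATATGTATCATATCTAGAGGTGTATAAGGTGCTCGTTATCCGAAAAAAC
ACACCACAGGAACGGTTCGACAAAAGATTAAACAACAAGGCCTTTGCCGTGAACTAA
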