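>ex4 synthetic stand-in, RPS24-like donor exon
ATGGCCTGTATGAGAAGAAACGTCAGATGGTCATTGATGTCCTGCACGGTGGCAAGGCGA
>m3 synthetic stand-in, 3-nt microexon (one lysine codon)
AAG
>m18 synthetic stand-in, 18-nt microexon
GACTACAAGCACCAGCTG
>m22 synthetic stand-in, 22-nt microexon with in-frame stop
GGTAAATAAGCTGCTGCTGCTG
>ex6 synthetic stand-in, terminal exon (PKE then stop at its start)
CCAAAAGAGTAAACCGGTACGTTAGCCTAGGCATCGATTACGGCTAAGCTTACGGATCCATGCAATCGGTACCAGTTAGCCTGCAATGATGTTAGCTGTG
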