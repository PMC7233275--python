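>A synthetic atpI-atpH intergenic spacer allele (217 bp)
GACCTATCGGTATAGTATTGTATTTTTTAAGAAACTGATAAATAGTTAGTTGTCTTTATTTTTATCGAAT
TTCATGTATATCTCCAAATGTATGCTGTTTCACATTCGCACAGACGTTAAACGTTCACCTGATAAGGTAC
TTATAGCAATATAGAATTGTTTTCATTTGGGTATATTACAGAGTAGGATCGAGTTTTTCTGTAAACAATT
ATATCTT
>B synthetic atpI-atpH intergenic spacer allele (217 bp)
GACCTATCGGTATAGTATTGTATTTTTTAAGAAACTGATAAATAGTTAGTTGGCTTTATTTTTATCGAAT
TTCATGTATATCTCCAAATGTATGCTGTTTCACATTCGCACAGACGTTAAACGTTCACCTGATAAGGTAC
TTATAGCAATATAGAATTGTTTTCATTTGGGTATATTACAGAGTAGGATCGAGTTTTTCTGTAAACAATT
ATATCTT
>C synthetic atpI-atpH intergenic spacer allele (217 bp)
GACCTATCGGTATAGTATTGTATTTTTTAAGAAACTGATAAATAGTTAGTTGTATTTATTTTTATCGAAT
TTCATGTATATCTCCAAATGTATGCTGTTTCACATTCGCACAGACGTTAAACGTTCACCTGATAAGGTAC
TTATAGCAATATAGAATTGTTTTCATTTGGGTATATTACAGAGTAGGATCGAGTTTTTCTGTAAACAATT
ATATCTT
>D synthetic atpI-atpH intergenic spacer allele (217 bp)
GACCTATCGGTATAGTATTGTATTTTTTAAGAAACTGATAAATAGTTAGTTGTCTTTATTTTTATCGAAT
TTCATGTATATCTCCAAATGTATGTTGTTTCACATTCGCACAGACGTTAAACGTTCACCTGATAAGGTAC
TTATAGCAATATAGAATTGTTTTCATTTGGGTATATTACAGAGTAGGATCGAGTTTTTCTGTAAACAATT
ATATCTT
>E synthetic atpI-atpH intergenic spacer allele (217 bp)
GACCTATCGGTATAGTATTGTATTTTTTAAGAAACTGATAAATAGTTAGTTGTCTTTATTTTTATCGAAT
TTCATGTATATCTCCAAATGTATGCTGTTTCACATTCGCACAGACGTTAAACGTTCACCTGATAAGGTAC
TTATAGCAATATAGAATTGTTTTCATTTGGGTATATTACAGAGTAGGATCGAGTTTTTCTGTAAACAATT
ATATCTT
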