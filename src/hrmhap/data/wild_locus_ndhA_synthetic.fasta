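>A synthetic ndhA intron allele (344 aligned columns)
TAAGGATTATCCAACTATATGCTTATCTTGGACAACATGAATTACTATTGTTTCCTAATCTGTAGCTAAC
TATATTTTTTTCACATGGTTTTAAATTCGGATAAGTTATATTGTTGTAAGCCAAGTTTACTTCGTATCCC
CAAAACACCGTAAACCATAAAGTTATTTATTAATCACTGGCAAATTTCATATTTGGTTGATGGACGCATA
AATGTATATATGTAGATTTAATTTAAGTCTAATGTCTATTCTTTCTATGTGGCCATTTTAATGCAGATCT
CTAAAGAAATTATGAACCTGTGCTTACATAATTTGTACGCTATTAATATATAGGTGTGAATTAT
>B synthetic ndhA intron allele (344 aligned columns)
TAAGGATTATCCAACTATATGCTTATCTTGGACAACATGAATTACTATTGTTTCCTAATCTGTAGCTAAC
TATATTTTTTTCACATGGTTTTAAATTCGGATAAGTTATATTGTTGTAAGCCAAGTTTACTTCGTATCCC
CAAAACACCGTAAACCATAAAGTTATTTATTAATCACTGGCAAATTTCATATTTGGTTGATGGACGCATA
AATGTATATATGTAGATTTAATTTAAGTCTAATGTCTATTCTTTCTATGTGGCCATTTTAATGCAGATCT
CTAAAGAAATTATGAACCTGTGCTTACATAATTTGTACGCTATTAATATATAGGTGTGAATTAT
>C synthetic ndhA intron allele (344 aligned columns)
TAAGGATTATCCAACTATATGCTTATCTTGGACAACATGAATTACTATTGTTTCCTAATCTGTAGCTAAC
TATATTTTTTTCACATGGTTTTAAATTCGGATAAGTTATATTGTTGTAAGCCAAGTTTACTTCGTATCCC
CAAAACACCTTAAACCATAAAGTTATTTATTAATCACTGGCAAATTTCATATTTGGTTGATGGACGCATA
AATGTATATATGTAGATTTAATTTAAGTCTAATGTCTATTCTTTCTATGTGGCCATTTTAATGCAGATCT
CTAAAGAAATTATGAACCTGTGCTTACATAATTTGTACGCTATTAATATATAGGTGTGAATTAT
>D synthetic ndhA intron allele (344 aligned columns)
TAAGGATTATCCAACTATATGCTTATCTTGGACAACATGAATTACTATTGTTTCCTAATCTGTAGCTAAC
TATATTTTTTTCACATGGTTTTAAATTCGGATAAGTTATATTGTTGTAAGCCAAGTTTACTTCG
-------AAAACACCGTAAACCATAAAGTTATTTATTAATCACTGGCAAATTTCATATTTGGTTGATGGA
CGCATAAATGTATATATGTAGATTTAATTTAAGTCTAATGTCTATTCTTTCTATGTGGCCATTTTAATGC
AGATCTCTAAAGAAATTATGAACCTGTGCTTACATAATTTGTACGCTATTAATATATAGGTGTGAATTAT
>E synthetic ndhA intron allele (344 aligned columns)
TAAGGATTATCCAACTATATGCTTATCTTGGACAACATGAATTACTATTGTTTCCTAATCTGTAGCTAAC
TATATTTTTTTCACATGGTTTTAAATTCGGATAAGTTATATTGTTGTAAGCCAAGTTTACTTCGTATCCC
CAAAACACCGTAAACCATAAAGTTATTTATTAATCACTGGCAAATTTCATATTTGGTTGATGGACGCATA
AATGTATATCTGTAGATTTAATTTAAGTCTAATGTCTATTCTTTCTATGTGGCCATTTTAATGCAGATCT
CTAAAGAAATTATGAACCTGTGCTTACATAATTTGTACGCTATTAATATATAGGTGTGAATTAT
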