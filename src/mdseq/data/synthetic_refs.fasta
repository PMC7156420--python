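>kras_ex1_nt
ATGACGTTGTATACGACGGCGGCGCAGGGGATTGGTGGCTCGCTTCTGCCCAAACTCTGGCCTCATCCCCAGCATGGGATCACCCTGCAAACGTCCTGGCTAGGACCCCCC
>kras_ex1_t
GGGGGGTCCTAGCCAGGACGTTTGCAGGGTGATCCCATGCTGGGGATGAGGCCAGAGTTTGGGCAGAAGCGAGCCACCAATCCCCTGCGCCGCCGTCGTATACAACGTCAT
>kras_ex2_nt
GCGGTCATCCTCAAGCCCGATGCCCGAAACCAACGGAAGTCTGGACAGCGAGAATTGGCTCGGTGTCGAACTCTGCTGTTCAACAATACG
>kras_ex2_t
CGTATTGTTGAACAGCAGAGTTCGACACCGAGCCAATTCTCGCTGTCCAGACTTCCGTTGGTTTCGGGCATCGGGCTTGAGGATGACCGC
>hras_ex2_nt
CTTTGGTTCCCACTCGAGGGTGACCTACGCCAAGATCTTAATACGGGAATTACAGAATTAAACTATGGTTGGCTCAGGGCCCGTGTGTTC
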