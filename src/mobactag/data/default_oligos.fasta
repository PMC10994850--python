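>a sub_lengths=9,10,10,9
CGGAAGGTAGCGGCTTGACGGTTCCATCCTCATTGTTC
>b sub_lengths=9,10,10,9
GCACTTCCTTCCTTCCGCTACGTGCCTCGTGTGACACT
>c sub_lengths=9,10,10,9
TAACGTTCTGAGTTCCGTAGCCAATCTGCTCGTTAACA
>d sub_lengths=9,10,10,9
GTTAATACGAGTCGCTTAACTCTAACTGCCTAACTGAC
>e sub_lengths=10,9,10,9
ACCACGTCCAATGGTTGCCTGGCTTAGGATTGATGCCT
>f sub_lengths=10,10,9,9
ATTAGCGCATAGTACATCGTGGTAAGGTGAATGAGCCG
>g sub_lengths=10,9,9,10
TACTGTATAGCAAGGTATATCCTATTAACAGCGTATTC
>h sub_lengths=10,9,10,9
ACAATCTACCGACTTCATACCGCTGGCAGATAATCATC
>i sub_lengths=9,10,9,10
AGTGGCATATAGCATGGCAACTGGTCATTAAGAGACAG
>j sub_lengths=10,10,8,10
TCTTAGCGTGATAGCCAACGACGTGTGCAATGACGAAG
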