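>Podo-1
GCTTTTTCCGGGGAGGTGGTCTAGGTGGTCGGCCACGAGCTCCCAAATTTTCGCCCCAT
>Podo0
GGCTTTTTCCGGGGAGGTGGTCTAGGTGGTCGGCCACGAGCTCCCAAATTTTCGCCCCAT
>IBV-Podo-1_sp6
TATTTAAACGGGTACGGGAGGTGGTCAAGGTGGTCGGCCACGAGCTCCCAAATTTTCGCCCC
>IBV-Podo-1_sp2
TATTTAAACCGGGGAGGTGGTCTAGGTGGTCGGCCACGAGCTCCCAAATTTTCGCCCCA
>IBV-Podo0
TTATTTAAACGGGTACGGGAGGTGGTCAAGGTGGTCGGCCACGAGCTCCCAAATTTTCGCCCCAT
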