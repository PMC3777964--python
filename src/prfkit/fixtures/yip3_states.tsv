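# 3'-ORF (C-terminal extension) presence in YIP3 orthologs
Podospora_anserina	present
Neurospora_crassa	present
Grosmannia_clavigera	present
Botrytis_cinerea	present
Mycosphaerella_graminicola	present
Cladosporium_fulvum	present
Aspergillus_nidulans	present
Ascosphaera_apis	absent
Tuber_melanosporum	present
Arthrobotrys_oligospora	absent
Saccharomyces_cerevisiae	absent
Candida_albicans	absent
Schizosaccharomyces_pombe	absent
Ustilago_maydis	absent
Cryptococcus_neoformans	absent
Rhizopus_oryzae	absent
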