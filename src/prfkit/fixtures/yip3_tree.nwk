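((((((((Podospora_anserina,Neurospora_crassa),Grosmannia_clavigera)Sordariomycetes,(Botrytis_cinerea)Leotiomycetes),((Mycosphaerella_graminicola,Cladosporium_fulvum)Dothideomycetes,(Aspergillus_nidulans,Ascosphaera_apis)Eurotiomycetes)),(Tuber_melanosporum)Pezizomycetes)Pezizomycotina_core,(Arthrobotrys_oligospora)Orbiliomycetes)Pezizomycotina,((Saccharomyces_cerevisiae,Candida_albicans)Saccharomycotina,(Schizosaccharomyces_pombe)Taphrinomycotina))Ascomycota,((Ustilago_maydis,Cryptococcus_neoformans)Basidiomycota,(Rhizopus_oryzae)Mucoromycota))Eumycota;
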