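>G4_IX G4-forming 32-mer from S. cerevisiae chromosome IX
GGGTACGGTGGGTAATAAGGGAAGGTATCGGG
>G4_IXmut G-tract-disrupting mutant of G4_IX
GCGTACGGTGCGTAATAAGCGAAGGTATCGCG
>FRET_G4_strand Cy3-labeled G4-containing strand with hybridization handle
TGGCGACGGCAGCGACCATTTGGGTACGGTGGGTAATAAGGGAAGGTATCGGG
>FRET_biotin_strand Cy5/biotin-labeled complementary anchor strand
TGGTCGCTGCCGTCGCCA
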