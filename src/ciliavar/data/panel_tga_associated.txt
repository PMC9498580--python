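# Genes previously associated with TGA (syndromic entities and the
# NODAL/GDF1-DAND5 laterality pathway).  Reconstructed from the variant-bearing
# genes of the study tables plus the pathway genes named in the text; the full
# published panel is larger.
KDM6A
KMT2D
MEGF8
FOXH1
GDF1
NODAL
ACVR2B
DAND5
DNAI1
DISC1
CCDC65
SLC4A1
CLASP1
PLB1
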