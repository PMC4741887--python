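gene
KLF5
BIRC5
CCND1
CDC20
CDK4
CDKN1A
CDKN1B
CEBPB
CTGF
CXCL5
CYR61
EGFR
EGR1
FGF2
FGFBP1
FOS
FOXO1
HIF1A
HMGA2
IGF1R
IL6
ITGB1
JUN
KRT13
KRT14
LAMA3
MCM2
MKI67
MMP9
MYC
NFKB1
NOTCH1
PCNA
PDGFA
PDGFB
PLAU
PLK1
PTGS2
RELA
SERPINE1
SOX2
SP1
STAT3
TGFB1
TNFAIP3
TP63
VEGFA
WNT5A
YAP1
ZEB1
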