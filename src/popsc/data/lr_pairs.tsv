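ligand	receptor
TGFB1	TGFBR2
IL1B	IL1R1
TIMP1	CD63
IL18	CD48
TNFSF12	TNFRSF12A
TGFB2	TGFBR1
TGFB3	TGFBR2
IL6	IL6R
IL10	IL10RA
IL15	IL15RA
TNF	TNFRSF1A
TNF	TNFRSF1B
CXCL12	CXCR4
CCL2	CCR2
CCL5	CCR5
CSF1	CSF1R
HGF	MET
EGF	EGFR
VEGFA	FLT1
VEGFA	KDR
PDGFA	PDGFRA
PDGFB	PDGFRB
FGF2	FGFR1
IGF1	IGF1R
FN1	CD44
FN1	ITGA5
COL1A1	ITGB1
LAMB1	ITGA6
THBS1	CD47
JAG1	NOTCH1
DLL1	NOTCH2
ANGPT1	TEK
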