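RSPO3_LGR4	RSPO3	LGR4
JAG2_NOTCH1	JAG2	NOTCH1
NECTIN2_CD226	NECTIN2	CD226
CSF1_CSF1R	CSF1	CSF1R
CXCL12_CXCR4	CXCL12	CXCR4
KITLG_KIT	KITLG	KIT
GDNF_GFRA1	GDNF	GFRA1
BMP4_BMPR1A	BMP4	BMPR1A
DHH_PTCH1	DHH	PTCH1
INHBA_ACVR2A	INHBA	ACVR2A
WNT5A_FZD5	WNT5A	FZD5
TGFB1_TGFBR1	TGFB1	TGFBR1
FGF2_FGFR1	FGF2	FGFR1
IGF1_IGF1R	IGF1	IGF1R
NRG1_ERBB3	NRG1	ERBB3
DLL1_NOTCH2	DLL1	NOTCH2
PDGFA_PDGFRA	PDGFA	PDGFRA
EFNB1_EPHB2	EFNB1	EPHB2
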