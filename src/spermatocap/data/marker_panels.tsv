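SSC	UTF1
SSC	ID4
SSC	FGFR3
SSC	GFRA1
SSC	PIWIL4
Diff.ing SPG	LIN28A
Diff.ing SPG	DNMT3B
Diff.ing SPG	NANOS3
Diff.ing SPG	SALL4
Diff.ed SPG	SOHLH2
Diff.ed SPG	KIT
Diff.ed SPG	STRA8
Diff.ed SPG	DMRT1
L	PRDM9
L	SPO11
L	SYCE1
L	TEX12
Z	SYCP1
Z	MEIOB
Z	HORMAD1
Z	DMC1
P	PIWIL1
P	TDRD1
P	SPATA16
P	CCNA1
D	OVOL2
D	CCNB3
D	AURKC
D	SLC26A8
SPC7	TEX29
SPC7	TEX36
SPC7	SPATA8
SPC7	C2orf73
RS	ACR
RS	IZUMO1
RS	SPACA1
RS	TXNDC8
ST	WT1
ST	SOX9
ST	AMH
ST	CLDN11
MIX	ACTA2
MIX	MYH11
MIX	CYP17A1
MIX	INSL3
tMphi	CD68
tMphi	CD163
tMphi	LYZ
tMphi	C1QA
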