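g2m	HMGB2
g2m	CDK1
g2m	NUSAP1
g2m	UBE2C
g2m	BIRC5
g2m	TPX2
g2m	TOP2A
g2m	NDC80
g2m	CKS2
g2m	NUF2
g2m	CKS1B
g2m	MKI67
g2m	TMPO
g2m	CENPF
g2m	TACC3
g2m	FAM64A
g2m	SMC4
g2m	CCNB2
g2m	CKAP2L
g2m	CKAP2
g2m	AURKB
g2m	BUB1
g2m	KIF11
g2m	ANP32E
g2m	TUBB4B
g2m	GTSE1
g2m	KIF20B
g2m	HJURP
g2m	CDCA3
g2m	HN1
g2m	CDC20
g2m	TTK
g2m	CDC25C
g2m	KIF2C
g2m	RANGAP1
g2m	NCAPD2
g2m	DLGAP5
g2m	CDCA2
g2m	CDCA8
g2m	ECT2
g2m	KIF23
g2m	HMMR
g2m	AURKA
g2m	PSRC1
g2m	ANLN
g2m	LBR
g2m	CKAP5
g2m	CENPE
g2m	CTCF
g2m	NEK2
g2m	G2E3
g2m	GAS2L3
g2m	CBX5
g2m	CENPA
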