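g1s	MCM5
g1s	PCNA
g1s	TYMS
g1s	FEN1
g1s	MCM2
g1s	MCM4
g1s	RRM1
g1s	UNG
g1s	GINS2
g1s	MCM6
g1s	CDCA7
g1s	DTL
g1s	PRIM1
g1s	UHRF1
g1s	MLF1IP
g1s	HELLS
g1s	RFC2
g1s	RPA2
g1s	NASP
g1s	RAD51AP1
g1s	GMNN
g1s	WDR76
g1s	SLBP
g1s	CCNE2
g1s	UBR7
g1s	POLD3
g1s	MSH2
g1s	ATAD2
g1s	RAD51
g1s	RRM2
g1s	CDC45
g1s	CDC6
g1s	EXO1
g1s	TIPIN
g1s	DSCC1
g1s	BLM
g1s	CASP8AP2
g1s	USP1
g1s	CLSPN
g1s	POLA1
g1s	CHAF1B
g1s	BRIP1
g1s	E2F8
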