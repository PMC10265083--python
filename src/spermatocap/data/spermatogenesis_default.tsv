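spermatogenesis	DDX4
spermatogenesis	DAZL
spermatogenesis	BOLL
spermatogenesis	SYCP2
spermatogenesis	SYCE3
spermatogenesis	TEX11
spermatogenesis	TEX14
spermatogenesis	TEX15
spermatogenesis	MEIOC
spermatogenesis	TDRD5
spermatogenesis	TDRD6
spermatogenesis	TDRD9
spermatogenesis	MAEL
spermatogenesis	RNF17
spermatogenesis	PIWIL2
spermatogenesis	MOV10L1
spermatogenesis	TEX101
spermatogenesis	CATSPER1
spermatogenesis	CATSPER2
spermatogenesis	ODF1
spermatogenesis	ODF2
spermatogenesis	ODF3
spermatogenesis	AKAP3
spermatogenesis	AKAP4
spermatogenesis	SPAG6
spermatogenesis	SPAG16
spermatogenesis	SPATA4
spermatogenesis	SPATA6
spermatogenesis	SPATA9
spermatogenesis	SPATA18
spermatogenesis	SPATA22
spermatogenesis	TSSK2
spermatogenesis	TSSK3
spermatogenesis	TSSK4
spermatogenesis	TSKS
spermatogenesis	CABYR
spermatogenesis	FSCN3
spermatogenesis	TNP2
spermatogenesis	ZPBP
spermatogenesis	ZPBP2
spermatogenesis	SPAM1
spermatogenesis	ADAM2
spermatogenesis	ADAM30
spermatogenesis	IZUMO2
spermatogenesis	IZUMO4
spermatogenesis	SUN5
spermatogenesis	SPEM1
spermatogenesis	CCIN
spermatogenesis	CYLC1
spermatogenesis	CYLC2
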