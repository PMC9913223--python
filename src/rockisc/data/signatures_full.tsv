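holoclone	ANLN
holoclone	AURKB
holoclone	CCNA2
holoclone	CKAP2L
holoclone	FOXM1
holoclone	HMGB2
holoclone	LMNB1
clonogenic	KRT14
clonogenic	TP63
clonogenic	ITGA6
clonogenic	ITB1
clonogenic	BIRC5
differentiated	SERPINB3
differentiated	SFN
differentiated	KRT10
differentiated	TGM1
differentiated	IVL
differentiated	SPINK5
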