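PROSTATE_AGGRESSIVE_48	48-gene prognostic signature for aggressive prostate cancer	APOBEC3B	ASF1B	AURKB	BIRC5	BUB1B	CDC20	CDCA5	CDCA8	CDKN3	CEP55	DEPDC1B	DIP2B	DLGAP5	DNMT3B	DTL	EXO1	EZH2	FOXM1	GTSE1	HJURP	IQGAP3	KDM2B	KDM5B	KIAA0101	L2HGDH	LMNB1	LRPPRC	MELK	MYBL2	NAA15	NCAPG	PBK	PLK1	PTTG1	RAD51	RAD54L	RRM2	SPAG5	TET3	TK1	TMEM97	TOP2A	TPX2	TRIP13	TROAP	TTK	UBE2C	UHRF1
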