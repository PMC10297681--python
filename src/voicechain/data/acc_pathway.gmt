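ACC	Adenoid Cystic Carcinoma pathway	AKT1	ARID1A	ARID4B	ARID5B	ATM	ATRX	BCOR	BCORL1	BRCA1	BRD1	CEBPA	CMTR2	CNTN6	CREBBP	CTBP1	DTX4	EP300	ERBB2	ERBIN	FBXW7	FGF16	FGFR4	FOXO3	FOXP2	H1-4	H2AC16	HRAS	IL17RD	INSRR	JMJD1C	KANSL1	KAT6A	KDM6A	KDM6B	KMT2C	MAGI1	MAGI2	MAML3	MAP2K2	MAX	MGA	MORF4L1	MYB	MYBL1	MYC	MYCBP	MYCN	NCOR1	NFIB	NOTCH1	NSD1	PIK3CA	PRKDC	PTEN	RAF1	SETD2	SMARCA2	SMARCE1	SMC1A	SRCAP	TLK1	TP53	UHRF1
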