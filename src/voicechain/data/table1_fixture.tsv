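syndrome	implicated	vn1_count	vn1_connectivity	vn2_count	vn2_connectivity	effects
1p36	SPEN	1	10	226	3152	Del, or Abs
1q21.1-q21.2	RBM8A,GJAS	0	0	41	906	Del or Imp
1q41-q42	DISP1,LEFTY1,LEFTY2,BPNT1	0	0	60	1020	Apr
1q43-q44	AKT3	0	0	78	903	Del, Imp, or Abs
2p16.1-p15		0	0	17	508	Dys, Apr, or Imp
2p21	SLC3A1	0	0	24	557	Apr or Idio
2q23.1		0	0	2	31	Del or Imp
2q32-q33	COL3A1,COL5A2,GTF3C3,CASP8,CASP10	0	0	62	1429	Abs
2q37.3	HDAC4	0	0	38	330	Imp
3p13	FOXP1	0	0	8	48	Del, Idio, Imp and Dys (all severe), Apr
3q13.31	DRD3,GAP43,LSAMP	0	0	5	56	Imp or Abs
3q29	PAK2,DLG1	0	0	24	413	Del
4p16.3	FGFR3	1	25	44	495	Del or Abs
4q21		0	0	41	696	Del or Abs; Imp
5p (5p15.2 and/or (5p15.3 or 5p15.33))	TERT,CTNND2	0	0	37	500	Del, Abs, and Apr
5q14.3	MEF2C	0	0	7	275	Abs
5q33.1	RPS14	0	0	17	153	Dys
5q35.3	NSD1	1	8	47	653	Norm or Del
6pter-p24	FOXC1,GMDS	0	0	41	416	Del
6q25.3	ARID1B	0	0	21	363	Del, Apr, Dys
7p21	TWIST1	0	0	18	243	Del
7q11.23	ELN,LIMK1,GTF2IRD1,GTF2I	0	0	35	536	Norm or Del
8p23.1	GATA4	0	0	49	337	No significant anomaly reports
8q22.1	CCNE2	0	0	13	152	Del
8q24.11-q24.13	EXT1	0	0	21	211	Del
9p24.3		1	9	3	13	Del, Dys, Apr
9q34.3	EHMT1	1	62	46	718	Del, Apr and Abs
10pter-p13 or 10p14-p15.1	GATA3	0	0	49	796	Sensorineural hearing loss
10q23	PTEN,BMPR1A	1	107	59	1003	Del or Abs; Imp
10q26	DOCK1	0	0	48	708	Imp; Del
11p11.2-p12	EXT2	0	0	46	737	Idio, Dys, Del, Apr
11p13-p12	PAX6,SLC1A2,PRRG4	0	0	23	342	Imp
11p15.5	IGF2	1	347	50	1243	Imp
11q13.3	FGF4,FGF3,FADD	0	0	11	608	Del Imp
11q23		0	0	77	1421	Dysarthric, Abs; Imp
11q23.3-q25	FLI1,JAM3	0	0	119	1522	Imp, Del, Apr
12q14.3	HMGA2	0	0	9	108	Abs, Imp or Del
13q12.3		0	0	6	119	Del
13q14	RB1	0	0	46	595	Norm
13q22.3	EDNRB	0	0	3	37	Norm
13q33-q34	SOX1,ARHGEF7	0	0	30	635	Apr
14q11-q22	PAX9,SUPT16H,CHD8,RALGAPA1	0	0	173	2021	Del or Abs
14q22.1-q23.1	PTGDR,BMP4	0	0	41	530	Imp
14q32.2	DLK1,MEG3	0	0	23	242	Del; Idio
15q11.2	NIPA1,NIPA2,CYFIP1,TUBGCP5	0	0	11	72	Del
15q11-q13	NDN,SNRPN	0	0	30	230	Del or Imp
15q11-q13	UBE3A	0	0	same	same	Abs; Imp
15q13.3	CHRNA7,OTUD7A	0	0	8	47	Imp or Idio
15q24	SIN3A	0	0	38	623	Del or Imp
16p11.2	SH2B1,TBX6,CORO1A	1	1	70	1067	Apr; Dys, Del or Imp
16p12.2-p11.2	SH2B1	1	1	106	1682	Del or Imp
16p12.1		0	0	17	157	Del
16p13.11	MYH11	0	0	6	116	Del
16p13.3	CREBBP,TRAP1	1	140	122	1532	Apr, Dys, Imp or Del
16q22	CBFB	1	2	79	830	Not available
16q24.3-q24.2	CDH15,ZNF778,ZFPM1	0	0	28	307	Del or Imp
17p11.2	LLGL1,UBB	0	0	36	845	Del; Dys
17p13.1	KCNAB3,GUCY2D,TP53,TRAPPC1,MPDU1,FXR2,EFNB3	2	214	74	1387	Abs
17p13.3	PAFAH1B1,YWHAE	0	0	37	487	Del
17q11.2	NF1	0	0	40	620	No significant issues
17q12	HNF1B,LHX1,CCL3L3	1	124	59	890	Del or Imp
17q21.31	KANSL1,MAPT,CRHR1	2	68	46	740	Del or Abs
17q23.1-q23.2		0	0	28	307	Del
17q24.3-q24.2	ABCA5,MAP2K6,SOX9	0	0	22	720	Del
18q	MBP	0	0	122	1666	Del or Imp
19p13.13		2	263	131	2080	Del; Imp
19q13.11	UBA2,WTIP	1	23	22	283	Del or Abs; Imp
20p12.3	BMP2	0	0	13	415	Del or Imp
22q11.2	TBX1,COMT,TOP3B	0	0	66	1294	Apr, Dys, Del or Imp
22q12.2	NF2	0	0	27	253	Del or Imp
22q13.3	ARSA,SHANK3	1	9	45	670	Del or Abs
Xp11.3	RP2	1	6	20	335	Imp
Xp21	GK,DMD,NR0B1	0	0	7	121	Del
Xq28 (a)	ABCD1,BCAP31,SLC6A8	0	0	64	1053	Del
Xq28 (b)	MECP2	0	0	same	same	Norm to Abs
Yq11		0	0	6	40	Norm
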