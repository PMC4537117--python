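case_id	sex	diagnosis	candidate_genes	gene	transcript	mutations	consistency
P1	F	AxD	GFAP	GFAP	NM_001242376.1	c.236G>A (p.R79H)	Yes
P2	M	AS	COL4A4;COL4A5	COL4A5	NM_033380.2	c.1769A>C (p.K590T) (Hem), novel	Yes
P3	F	AS	COL4A4;COL4A5	COL4A5	NM_033380.2	c.2414G>T (p.G805V)	Yes
P4	F	AS	COL4A4;COL4A5	COL4A5	NM_033380.2	c.187G>T (p.G63*), novel	Yes
P5	M	APS-1?	AIRE	-	-	negative result	No
P6	M	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.9914_9915delCT (p.A3305Pfs*10), novel	Yes
P7	F	ADPKD	PKD1;PKD2	-	-	negative result	No
P8	F	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.7210-1G>A, novel	Yes
P9	M	ADPKD	PKD1;PKD2	-	-	negative result	No
P10	M	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.1589G>A (p.C530Y)	Yes
P11	M	ADPKD	PKD1;PKD2	-	-	negative result	No
P12	M	ADPKD	PKD1;PKD2	-	-	negative result	No
P13	F	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.7210-2A>G	Yes
P14	F	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.8698C>T (p.Q2900*)	Yes
P15	M	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.7204C>T (p.R2402*)	Yes
P16	M	ADPKD	PKD1;PKD2	-	-	negative result	No
P17	M	ADPKD	PKD1;PKD2	-	-	negative result	No
P18	M	ADPKD	PKD1;PKD2	-	-	negative result	No
P19	F	ADPKD	PKD1;PKD2	-	-	negative result	No
P20	M	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.7566C>A (p.C2522*), novel	Yes
P21	M	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.10618G>T (p.G3540*), novel	Yes
P22	M	ADPKD	PKD1;PKD2	-	-	negative result	No
P23	F	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.2085_2086insC (p.A696Rfs*18)	Yes
P24	F	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.9377C>T (p.T3126I)	Yes
P25	M	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.8350C>T (p.Q2784*)	Yes
P26	M	ADPKD	PKD1;PKD2	-	-	negative result	No
P27	M	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.9569G>T (p.G3190V), novel	Yes
P28	M	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.11721_11722insCT (p.L3909Cfs*37), novel	Yes
P29	M	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.11343C>A (p.Y3781*), novel	Yes
P30	F	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.6574_6580delACCGCCA (p.T2192Afs*18)	Yes
P31	M	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.12608_12635delGGCTGGGGACAAGGTGTGAGCCTGAGCC (p.R4203Pfs*93)	Yes
P32	F	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.8578C>T (p.Q2860*), novel	Yes
P33	M	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.12003+2T>C	Yes
P34	F	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.8590G>T (p.E2864*), novel	Yes
P35	F	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.12373C>T (p.Q4125*)	Yes
P36	F	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.12373C>T (p.Q4125*)	Yes
P37	M	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.5014_5015delAG (p.R1672Gfs*98)	Yes
P38	M	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.8590G>T (p.E2864*), novel	Yes
P39	F	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.7915C>T (p.R2639*)	Yes
P40	M	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.4306C>T (p.R1436*)	Yes
P41	F	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.7546C>T (p.R2516C)	Yes
P42	M	ADPKD	PKD1;PKD2	PKD1	NM_001009944.2	c.7546C>T (p.R2516C)	Yes
P43	-	ARCI	ALOX12B;ALOXE3	ALOXE3	NM_001165960.1	c.814C>T (p.R272*) (Hom), novel	Yes
P44	M	ARCI, carrier	ALOX12B;ALOXE3	ALOXE3	NM_001165960.1	c.814C>T (p.R272*), novel	Yes
P45	F	ARCI, carrier	ALOX12B;ALOXE3	ALOXE3	NM_001165960.1	c.814C>T (p.R272*), novel	Yes
P46	F	BS	SLC12A1;CLCNKB	-	-	negative result	No
P47	F	BS?	BSND;KCNJ1	CFTR	NM_000492.3	c.1116+1G>A c.3062C>T (p.P1021L), novel	CF
P48	M	BS?	BSND;KCNJ1	CFTR	NM_000492.3	c.2909G>A (p.G970D) (Hom)	CF
P49	F	CMT	AARS;EGR2	AARS	NM_001605.2	c.2042G>T (p.G681V), novel	Yes
P50	F	CMT	AARS;EGR2	EGR2	NM_001136177.1	c.928ins>GCC (p.Y310delinsCH), novel	Yes
P51	F	CMT	AARS;EGR2	-	-	negative result	No
P52	F	CMT	AARS;EGR2	PMP22	NM_153322.1	c.215C>T (p.S72L)	Yes
P53	M	CMT	AARS;EGR2	MFN2	NM_014874.3	c.1039-2A>G, novel	Yes
P53	M	CMT	AARS;EGR2	GJB1	NM_000166.5	c.265C>G (p.L89V) (Hem), novel	Yes
P54	M	CMT	AARS;EGR2	GJB1	NM_000166.5	c.223C>T (p.R75W) (Hem)	Yes
P55	F	CMT	AARS;EGR2	GDAP1	NM_018972.2	c.767A>G (p.H256R)	Yes
P56	M	CMT	AARS;EGR2	PMP22	NM_153322.1	CDS1-4 dup	Yes
P57	M	CMT	AARS;EGR2	GJB1	NM_000166.5	c.269T>C (p.L90P) (Hem), novel	Yes
P58	F	Congenital Afibrinogenemia	FGA;FGB;FGG	FGA	NM_000508.3	c.1368delC (p.T457Rfs*27) (Hom), novel	Yes
P59	F	CDA?	CDAN1;SEC23B;KLF1	PKLR	NM_000298.5	c.1528C>T (p.R510*) c.661G>A (p.D221N)	PK Deficiency
P60	-	CdLS	NIPBL;SMC1A	NIPBL	NM_133433.3	c.2207_2211delCAAAG (p.Q738Rfs*2), novel	Yes
P61	M	Dent Disease	CLCN5;OCRL	OCRL	NM_000276.3	c.215_216delTT (p.L73Dfs*2) (Hem)	Yes
P62	M	Dent Disease	CLCN5;OCRL	CLCN5	NM_001127899.1	c.778_798delACTCTGGTTATCAAAACCATC (p.T260_I266del) (Hem), novel	Yes
P63	F	FHL	PRF1;STX11	PRF1	NM_005041.4	c.1620A>G (p.Q540Q)	Yes
P64	F	GS	SLC12A3;CLCNKB	SLC12A3	NM_000339.2	c.1202C>T (p.A401V) (Hom), novel	Yes
P65	-	GSD?	AGL;ALDOA	GALT	NM_000155.3	c.1043A>G (p.D348G) (Hom), novel	Galactosemia
P66	M	Hereditary Muscular Disease?	ACTA1;ATP1A3	-	-	negative result	No
P67	M	HSAN	IKBKAP;NTRK1	NTRK1	NM_002529.3	c.963delG (p.L322Sfs*148), novel c.851-33T>A	Yes
P68	-	Hypochondroplasia?	FGFR3	COL2A1	NM_001844.4	c.863G>C (p.G288A), novel	Yes
P68	-	Hypochondroplasia?	FGFR3	LBR	NM_194442.2	c.1640A>G (p.N547S), novel c.1757G>A (p.R586H), novel	Yes
P69	M	Hypophosphatasia	ALPL	ALPL	NM_000478.4	c.98C>T (p.A33V) (Hom)	Yes
P70	F	IP	IKBKG	-	-	negative result	No
P71	M	IBD deficiency? EE? SCAD Deficiency?	ACAD8;ETHE1;ACADS	ACADS	NM_000017.2	c.989G>A (p.R330H) c.1031A>G (p.E344G)	Yes
P72	M	IBD deficiency? EE? SCAD Deficiency?	ACAD8;ETHE1;ACADS	ACADS	NM_000017.2	c.164C>T (p.P55L) c.1031A>G (p.E344G)	Yes
P73	F	LPG	APOE	APOE	NM_000041.2	c.127C>T (p.R43C)	Yes
P74	M	MMA, carrier	MUT;MMAA	MMACHC	NM_015506.2	c.656_658delAGA (p.K220del)	Yes
P75	F	MMA, carrier	MUT;MMAA	MMACHC	NM_015506.2	c.609G>A (p.W203*)	Yes
P76	M	Microphthalmia	SOX2;OTX2	OTX2	NM_021728.3	c.538C>T (p.Q180*), novel	Yes
P77	F	Mucopolysaccharidosis	ARSB;GALNS	GNPTAB	NM_024312.4	c.3565C>T (p.R1189*) c.2590_2591insG (p.E864Gfs*4)	Mucolipidosis
P78	F	Mucopolysaccharidosis, carrier?	ARSB;GALNS	-	-	negative result	No
P79	M	Mucopolysaccharidosis, carrier?	ARSB;GALNS	-	-	negative result	No
P80	F	OCA	GPR143;TYR	TYR	NM_000372.4	c.455C>A (p.P152H), novel c.832C>T (p.R278*)	Yes
P81	F	MCPH	MCPH1;WDR62	-	-	negative result	No
P82	M	PCD?	DNAI1;DNAH5	-	-	negative result	No
P83	M	SLSN	CEP290;IQCB1	IQCB1	NM_001023570.2	c.1225C>T (p.Q409*), novel c.1090C>T (p.R364*)	Yes
P84	F	SRNS?	ACTN4;ALG1	-	-	negative result	No
P85	F	SRNS?	ACTN4;ALG1	-	-	negative result	No
P86	F	WAS? X-SCID?	WAS;IL2RG	RAG1	NM_000448.2	c.874T>C (p.S292P), novel c.1328G>A (p.R443K), novel	OS
P87	M	XLA	BTK	BTK	NM_000061.2	c.1684C>T (p.R562W) (Hem)	Yes
P88	-	Trisomy 10	-	-	-	47.XX,+10	Yes
P89	-	Trisomy 9	-	-	-	47.XX,+9	Yes
P90	-	SMS	-	-	-	46,XN,del(17)(p11.2)	Yes
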