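entrez	symbol	direction	p_sdh	p_gomes	p_greenawalt	p_hao	count_printed	fold_sdh	fold_gomes	fold_greenawalt	fold_hao	refs
125	ADH1B	down	3E-05		0.002	0.0119	3/4	-2.3		-2.1	-3.6
126	ADH1C	down	2E-12	-	8E-07	0.0072	3/3	-4.8	-	-2.1	-6.7
760	CA2	down	3E-08	-	3E-09	0.0323	3/3	-5.1	-	-3.6	-4.3	Kimchi,Wang,Stairs,Razvi
957	ENTPD5	down	2E-07	-	3E-06	0.0118	3/3	-2.2	-	-3.5	-22.5
1159	CKMT1A	down	0.0022	0.0064	2E-06	0.007	4/4	-1.9	-2.1	-2.0	-2.3
1646	AKR1C2	down	0.002		0.0047	0.0219	3/4	-4.0		-2.1	-2.7
3248	HPGD	down	7E-06	0.0008	2E-08		3/4	-5.3	-7.8	-6.1
3373	HYAL1	down	4E-11	-	4E-08	0.0165	3/3	-2.9	-	-3.8	-7.2	Barrett
4588	MUC6	down	2E-11	-	6E-05	0.043	3/3	-13.1	-	-4.2	-11.6	Ostrowski,Barrett
4640	MYO1A	down	3E-11		5E-06	0.0365	3/4	-2.3		-2.9	-5.2
5873	RAB27A	down	3E-08		3E-05	0.005	3/4	-2.3		-2.2	-2.5
6819	SULT1C2	down	3E-10		2E-09	0.0086	3/4	-2.2		-2.8	-13.3	ElSerag
7031	TFF1	down	2E-08	-	3E-10	0.0049	3/3	-5.7	-	-3.2	-5.1	ElSerag,Fox,Ostrowski,Stairs,vanBaal2,Razvi
8513	LIPF	down	5E-08	-	0.0001	0.0447	3/3	-32.2	-	-5.2	-154.0	Razvi
11199	ANXA10	down	1E-11	-	4E-09	0.0089	3/3	-6.5	-	-3.1	-11.1	Kimchi,ElSerag,vanBaal2,Razvi
23584	VSIG2	down	3E-09		1E-08	0.012	3/4	-6.0		-2.3	-3.5
54474	KRT20	down	2E-10		4E-07	0.0145	3/4	-4.2		-7.5	-2.8	Helm,Stairs,vanBaal2,Razvi
57016	AKR1B10	down	1E-06		0.0003	0.018	3/4	-5.7		-2.4	-4.3
1278	COL1A2	up	0.0007	-	4E-07	0.0287	3/3	2.8	-	3.8	2.2
1282	COL4A1	up	7E-05	7E-06	0.0078	0.046	4/4	4.8	3.2	3.2	10.3
1284	COL4A2	up	0.0003	-	3E-07	0.0105	3/3	2.1	-	2.4	5.2	Wang
1290	COL5A2	up	0.0007	-	0.0074	0.0266	3/3	2.4	-	17.5	5.8
1293	COL6A3	up	0.0012		1E-06	0.0396	3/4	2.0		2.1	7.3
3490	IGFBP7	up	0.0001	-	3E-08	0.0366	3/3	2.5	-	2.2	5.0	Wang,Razvi
5328	PLAU	up	2E-05	0.0047	0.0004		3/4	4.1	3.5	4.9
6772	STAT1	up	0.0005	-	2E-05	0.0442	3/3	2.1	-	3.7	3.7
23636	NUP62	up	2E-05		3E-05	0.0485	3/4	2.6		4.0	2.4
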