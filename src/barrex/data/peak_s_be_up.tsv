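entrez	symbol	direction	p_sdh	p_gomes	p_greenawalt	p_hao	count_printed	fold_sdh	fold_gomes	fold_greenawalt	fold_hao	refs
126	ADH1C	up	1.6E-12	-	8.1E-07	0.007	3/3	24.2	-	13.9	4.3
283	ANG	up	1.8E-13		8.4E-10	0.005	3/4	10.8		3.4	12.3
489	ATP2A3	up	1.5E-11	-	2.3E-08	0.021	3/3	5.7	-	6.4	7.8	Helm,Kimchi
563	AZGP1P1	up	4.2E-06		3.6E-06	0.022	3/4	3.5		3.7	9.6
629	CFB	up	6.9E-11	-	7.1E-07	0.016	3/3	6.0	-	3.2	6.1
760	CA2	up	2.7E-08	-	3.4E-09	0.032	3/3	12.2	-	13.1	11.8	Kimchi,Wang,Stairs,Razvi
1510	CTSE	up	1.5E-08	-	6.1E-09	0.006	3/3	3.2	-	29.8	41.5	Kimchi,ElSerag
1612	DAPK1	up	1.3E-10		2.2E-10	0.002	3/4	4.7		5.0	3.3
1803	DPP4	up	2.1E-08	0.0004	7.2E-07		3/4	3.6	3.6	19.3
2203	FBP1	up	1.3E-07		6E-08	0.009	3/4	12.5		8.4	8.3
2331	FMOD	up	3.8E-09		3.1E-06	0.016	3/4	4.9		9.4	14.7	Razvi
2705	GJB1	up	8.3E-13		1.5E-06	0.024	3/4	3.7		12.4	6.6	Wang
3158	HMGCS2	up	5.1E-12	0.0004	4.4E-11	0.048	4/4	14.6	3.3	19.0	21.6
3171	FOXA3	up	6.6E-13	-	3.9E-09	0.006	3/3	5.6	-	12.9	123.6	Wang
3217	HOXB7	up	1.7E-11	0.0005	9.7E-13	0.037	4/4	3.4	1.3	7.6	9.3	Kimchi
3373	HYAL1	up	4.4E-11	-	3.6E-08	0.017	3/3	9.0	-	6.9	11.9	Barrett
3783	KCNN4	up	4.5E-09	-	1E-09	0.006	3/3	3.1	-	3.7	9.2
3960	LGALS4	up	3.9E-10		5E-11	0.026	3/4	55.2		32.1	7.0	ElSerag,Fox,vanBaal2
4060	LUM	up	6.4E-05	0.0003	5.2E-05		3/4	4.9	3.3	3.2
4584	MUC3B	up	1.4E-07	-	1.7E-08	0.048	3/3	12.0	-	17.7	11.2
4588	MUC6	up	1.6E-11	-	6.1E-05	0.043	3/3	43.8	-	26.6	3.6	Ostrowski,Barrett
4640	MYO1A	up	2.7E-11		5.3E-06	0.037	3/4	11.0		14.6	11.5
4907	NT5E	up	3.1E-07	7E-05	2.8E-06	0.032	4/4	3.0	4.3	10.4	3.9
5264	PHYH	up	3.3E-11		2.7E-10	0.036	3/4	3.8		4.2	13.5
5332	PLCB4	up	4.1E-11	-	1.8E-08	0.005	3/3	3.6	-	4.2	19.7
5997	RGS2	up	0.0017		1.5E-06	0.019	3/4	3.7		9.8	4.3
6035	RNASE1	up	8E-10		3.4E-09	0.016	3/4	15.2		6.1	14.6	Razvi
6690	SPINK1	up	1.4E-10	-	7.8E-07	0.025	3/3	41.6	-	22.4	26.4	ElSerag,Ostrowski
6819	SULT1C2	up	3E-10		2.4E-09	0.009	3/4	5.2		58.5	28.3	ElSerag
7031	TFF1	up	1.7E-08	-	2.5E-10	0.005	3/3	123.7	-	53.7	7.4	ElSerag,Fox,Ostrowski,Stairs,vanBaal2,Razvi
7429	VIL1	up		2E-05	1.8E-09	0.033	3/4		5.6	21.2	34.1	ElSerag,Razvi
8513	LIPF	up	5.2E-08	-	0.00013	0.045	3/3	46.3	-	209.9	13.1	Razvi
8842	PROM1	up	1.1E-11		1.4E-09	0.023	3/4	10.1		18.5	4.8	ElSerag
8876	VNN1	up	4.6E-08	-	2.1E-07	0.045	3/3	3.4	-	10.8	4.6	Fox
8985	PLOD3	up	7.1E-12	-	7.7E-11	0.018	3/3	3.3	-	3.8	4.3
8991	SELENBP1	up	1.4E-12	-	3.5E-09	0.002	3/3	6.3	-	5.5	8.4
10008	KCNE3	up	1E-11	-	6.4E-08	0.027	3/3	9.2	-	8.6	14.4
10099	TSPAN3	up	8.6E-11		2.1E-06	0.034	3/4	5.8		3.8	10.1	Fox
10103	TSPAN1	up	1.3E-09	-	3.5E-11	0.004	3/3	58.3	-	63.5	54.5	ElSerag,Ostrowski,Razvi
10396	ATP8A1	up		1E-06	7.7E-06	0.041	3/4		24.6	3.5	6.8
10551	AGR2	up	5.6E-14	-	1.4E-11	0.003	3/3	35.5	-	27.4	17.0	Wang
10723	SLC12A7	up	6.1E-10	-	9E-11	0.007	3/3	3.6	-	4.1	4.1
10788	IQGAP2	up	2.3E-11	-	8.9E-12	0.027	3/3	5.0	-	15.6	4.5	ElSerag
10954	PDIA5	up	2.2E-13	-	2.3E-08	0.026	3/3	4.0	-	4.8	7.8
11015	KDELR3	up	6.2E-13		9.9E-11	0.025	3/4	6.0		8.0	9.4	Kimchi
11145	PLA2G16	up	6.2E-13	-	1.3E-10	0.009	3/3	7.3	-	8.4	7.6
11199	ANXA10	up	1.4E-11	-	3.5E-09	0.009	3/3	26.7	-	19.4	14.8	Kimchi,ElSerag,vanBaal2,Razvi
25945	PVRL3	up	9.9E-12	-	4.3E-07	0.009	3/3	3.6	-	8.8	47.9
30011	SH3KBP1	up	1.5E-05		2.4E-11	0.009	3/4	3.6		3.8	5.7
51703	ACSL5	up	1.2E-11	0.0004	4.3E-07	0.037	4/4	7.6	4.2	4.9	8.3
54474	KRT20	up	1.9E-10		3.5E-07	0.015	3/4	13.9		58.9	25.2	Helm,ElSerag,Stairs,vanBaal2
56654	NPDC1	up	4.2E-11	-	2.2E-05	0.016	3/3	3.9	-	3.8	4.0
81618	ITM2C	up	4.2E-13	-	1.3E-08	0.018	3/3	7.4	-	5.2	4.0
118429	ANTXR2	up	8.3E-06	-	9.9E-09	0.019	3/3	3.2	-	3.5	7.8
445329	SULT1A3	up	1.2E-07	-	4.9E-05	0.029	3/3	3.5	-	3.8	5.0
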