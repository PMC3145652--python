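entrez	symbol	direction	p_sdh	p_gomes	p_greenawalt	p_hao	count_printed	fold_sdh	fold_gomes	fold_greenawalt	fold_hao	refs
360	AQP3	down	1.3E-10	0.0004	2.9E-07	0.009	4/4	-7.6	-3.4	-6.6	-2.3	Kimchi
379	ARL4D	down	7.8E-11		6.8E-14	0.043	3/4	-3.6		-7.1	-10.7	Kimchi,Wang
390	RND3	down	9.4E-05	-	1.5E-06	0.002	3/3	-3.5	-	-4.6	-4.8
646	BNC1	down	0.0012	6E-05	2.2E-11	0.041	4/4	-1.3	-3.3	-6.1	-4.1
810	CALML3	down	2.6E-09	-	3.7E-07	0.033	3/3	-22.2	-	-7.2	-3.1	Kimchi
874	CBR3	down	1.2E-06	0.0001	1E-09	0.028	4/4	-3.0	-4.5	-3.6	-4.1	Wang
978	CDA	down	3.2E-07	2E-05	1E-10		3/4	-5.2	-3.6	-4.2		Wang
1382	CRABP2	down	1.5E-09		2.2E-12	0.024	3/4	-12.5		-6.0	-6.7	Wang
1410	CRYAB	down	8.3E-11	-	0.00037	0.035	3/3	-6.4	-	-3.7	-4.2
2012	EMP1	down	7.4E-08	9E-05	1.3E-07	-	3/3	-6.8	-33.8	-3.4	-	Kimchi,Wang,Razvi
2125	EVPL	down	5.3E-10	0.003	7.2E-08	0.027	4/4	-7.0	-7.8	-5.3	-5.5	Barrett
5292	PIM1	down	2.8E-06	0.0001	5.9E-05	0.028	4/4	-3.7	-4.5	-8.0	-10.2	Kimchi
5493	PPL	down	6.9E-10	-	4.4E-09	0.017	3/3	-11.8	-	-5.6	-5.5	Kimchi,Wang
10848	PPP1R13L	down	6.4E-06	0.0018	1.6E-10		3/4	-3.1	-3.7	-4.7
23136	EPB41L3	down	6.7E-12	-	3.5E-11	0.012	3/3	-5.4	-	-5.5	-9.8
23328	SASH1	down	1.7E-05	8E-06	5.5E-10	0.01	4/4	-3.2	-7.0	-7.3	-8.2	Kimchi
23650	TRIM29	down	2.1E-08		2.7E-08	0.019	3/4	-5.5		-7.1	-4.4	Kimchi,Wang
26085	KLK13	down	9.2E-09	2E-05	0.00055		3/4	-10.0	-30.9	-5.7		Kimchi
26353	HSPB8	down	1.1E-08		2.2E-12	0.02	3/4	-6.0		-7.8	-8.2
27076	LYPD3	down	5.8E-09	-	1.6E-14	0.002	3/3	-7.8	-	-7.3	-7.9
57162	PELI1	down	0.0019	0.0029	4.1E-08	0.005	4/4	-2.0	-3.8	-8.1	-3.8
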