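hgnc_id	symbol	description	alias1	alias2	ref_count	refs
6441	KRT4	keratin 4	CYK4	CK4	8	Gomes,Kimchi,Hao,Wang,Fox,Barrett,Stairs,vanBaal2
6415	KRT13	keratin 13	MGC3781	CK13	7	Kimchi,Hao,Fox,Ostrowski,Barrett,Stairs,vanBaal2
6442	KRT5	keratin 5	EBS2	KRT5A	7	Kimchi,Greenawalt,Fox,Ostrowski,Stairs,vanBaal2
11755	TFF1	trefoil factor 1	HPS2	D21S21	7	Greenawalt,ElSerag,Fox,Ostrowski,Stairs,vanBaal2,Razvi
6446	KRT8	keratin 8	CARD2	CYK8	6	Hao,Wang,ElSerag,Barrett,Stairs,vanBaal2
534	ANXA10	annexin A10	ANX14		5	Kimchi,Greenawalt,ElSerag,vanBaal2,Razvi
1373	CA2	carbonic anhydrase II	CAII	CA-II	5	Kimchi,Wang,Greenawalt,Stairs,Razvi
3555	FABP1	fatty acid binding protein 1, liver	L-FABP		5	Helm,Wang,ElSerag,Fox,vanBaal2
6443	KRT6A	keratin 6A	KRT6C	CK6C	5	Kimchi,Wang,Fox,Stairs,vanBaal2
6444	KRT6B	keratin 6B	KRTL1		5	Kimchi,Hao,Fox,Stairs,vanBaal2
10492	S100A2	S100 calcium binding protein A2	S100L	CAN19	5	Kimchi,Wang,Greenawalt,Fox,Razvi
11757	TFF3	trefoil factor 3 (intestinal)			5	Greenawalt,ElSerag,Ostrowski,Stairs,vanBaal2
3333	EMP1	epithelial membrane protein 1	TMP	CL-20	4	Kimchi,Wang,Greenawalt,Razvi
6187	IVL	involucrin			4	Kimchi,Greenawalt,Fox,Barrett
6412	KRT1	keratin 1	EHK1	KRT1A	4	Wang,Fox,Stairs,vanBaal2
6416	KRT14	keratin 14	EBS3	EBS4	4	Kimchi,Fox,Stairs,vanBaal2
6427	KRT17	keratin 17	PCHC1		4	Hao,Fox,Stairs,vanBaal2
20412	KRT20	keratin 20	CK20	K20	4	Helm,ElSerag,Stairs,vanBaal2
6445	KRT7	keratin 7	K2C7	CK7	4	Barrett,Stairs,vanBaal2,Razvi
6565	LGALS4	lectin, galactoside-binding, soluble, 4	GAL4		4	Greenawalt,ElSerag,Fox,vanBaal2
7512	MUC2	mucin 2, oligomeric mucus/gel-forming			4	Helm,Greenawalt,Barrett,Stairs
7515	MUC5AC	mucin 5AC, oligomeric mucus/gel-forming			4	Greenawalt,Ostrowski,Barrett,Stairs
9273	PPL	periplakin			4	Gomes,Kimchi,Wang,Greenawalt
10498	S100A8	S100 calcium binding protein A8		CFAG	4	Kimchi,Hao,Fox,Razvi
10499	S100A9	S100 calcium binding protein A9	CAGB	CFAG	4	Kimchi,Greenawalt,Fox,Razvi
11244	SPINK1	serine peptidase inhibitor, Kazal type 1	Spink3	PCTT	4	Hao,Greenawalt,ElSerag,Ostrowski
11263	SPRR2C	small proline-rich protein 2C (pseudogene)			4	Kimchi,Hao,Wang,Greenawalt
11756	TFF2	trefoil factor 2	SML1		4	Ostrowski,Stairs,vanBaal2,Razvi
328	AGR2	anterior gradient homolog 2 (Xenopus laevis)	XAG-2	HAG-2	3	Hao,Wang,Greenawalt
533	ANXA1	annexin A1	ANX1	LPC1	3	Kimchi,Wang,Greenawalt
546	ANXA8	annexin A8	ANX8		3	Kimchi,Wang,Greenawalt
1805	CDX1	caudal type homeobox 1			3	Fox,Barrett,Stairs
2481	CSTA	cystatin A (stefin A)	STF1		3	Hao,Wang,Greenawalt
2500	CTGF	connective tissue growth factor	IGFBP8	CCN2	3	Helm,Hao,Razvi
2530	CTSE	cathepsin E			3	Kimchi,Greenawalt,ElSerag
3153	ECM1	extracellular matrix protein 1			3	Wang,Greenawalt,Razvi
3690	FGFR3	fibroblast growth factor receptor 3	JTK4	CEK2	3	Kimchi,Greenawalt,Ostrowski
4164	GAST	gastrin			3	Gomes,Fox,Razvi
4174	GATA6	GATA binding protein 6			3	Kimchi,Greenawalt,ElSerag
5476	IGFBP7	insulin-like growth factor binding protein 7	MAC25	IGFBP-7	3	Hao,Wang,Razvi
6361	KLK13	kallikrein-related peptidase 13	KLK-L4		3	Gomes,Kimchi,Greenawalt
6413	KRT10	keratin 10	KPP	CK10	3	Greenawalt,Stairs,vanBaal2
6421	KRT15	keratin 15	K15	CK15	3	Kimchi,Fox,Stairs
7511	MUC13	mucin 13, cell surface associated	DRCC1		3	Gomes,ElSerag,Stairs
7517	MUC6	mucin 6, oligomeric mucus/gel-forming			3	Greenawalt,Ostrowski,Barrett
17190	OLFM4	olfactomedin 4	OlfD	GW112	3	ElSerag,Fox,Razvi
8890	PGC	progastricsin (pepsinogen C)			3	Helm,Fox,Razvi
9053	PLAUR	plasminogen activator, urokinase receptor	CD87		3	Kimchi,Wang,Barrett
16	SERPINA3	serpin peptidase inhibitor, clade A, member 3	AACT		3	Helm,Greenawalt,Razvi
10569	SERPINB3	serpin peptidase inhibitor, clade B, member 3		SCCA1	3	Kimchi,Wang,Greenawalt
9490	TMPRSS15	transmembrane protease, serine 15			3	Helm,Fox,Barrett
17274	TRIM29	tripartite motif-containing 29	ATDC	FLJ36085	3	Kimchi,Wang,Greenawalt
20657	TSPAN1	tetraspanin 1	TSPAN-1	NET-1	3	ElSerag,Ostrowski,Razvi
11855	TSPAN8	tetraspanin 8	TM4SF3	CO-029	3	Gomes,Kimchi,Wang
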