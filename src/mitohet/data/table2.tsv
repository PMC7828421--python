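pair	sample	class	hgvs	major	minor	maf	depth	poisson_p	gene	effect	af_mitomap
2	DG33	c	m.10873T>C	C	T	0.014	11859	5.0e-147	ND4	p.Pro38=	0.336
2	DG33	c	m.14668C>T	T	C	0.011	4713	2.0e-82	ND6	p.Met2=	0.041
2	DG33	c	m.14783T>C	C	T	0.011	13425	3.0e-67	CYTB	p.Leu13=	0.212
2	DG33	c	m.15301G>A	A	G	0.019	10341	2.0e-23	CYTB	p.Leu185=	0.287
2	DG33	c	m.15326A>G	A	G	0.022	14117	2.0e-13	CYTB	p.Thr194Ala	0.987
2	DG34	m	m.6802A>G	A	G	0.014	37167	8.0e-302	COX1	p.Asp300Gly	-
4	DG76	m	m.15786T>C	T	C	0.013	66261	6.0e-04	CYTB	p.Phe347Ser	-
5	DG132	c	m.9507T>C	T	C	0.152	55188	3.0e-62	COX3	p.Phe101Leu	-
5	DG133	m	m.9507T>C	T	C	0.356	61348	0.0	COX3	p.Phe101Leu	-
6	DG161	m	m.5492T>C	T	C	0.012	29462	0.0	ND2	p.Pro341=	0.003
7	DG179	c	m.150C>T	C	T	0.256	19122	4.0e-123	Dloop	-	0.134
7	DG179	c	m.1316T>C	T	C	0.105	21577	6.0e-09	RNR1	-	-
7	DG179	c	m.5054G>A	G	A	0.02	70310	0.0	ND2	p.Pro195=	0.004
7	DG180	m	m.150C>T	C	T	0.015	19275	1.0e-92	Dloop	-	0.134
8	DG184	m	m.15591G>A	G	A	0.023	26908	0.0	CYTB	p.Arg282Gln	-
11	DG222	c	m.16290C>T	T	C	0.32	13735	2.0e-66	Dloop	-	0.039
12	DG224	c	m.6190G>A	G	A	0.011	8443	2.0e-126	COX1	p.Arg96His	-
12	DG224	c	m.10075T>C	T	C	0.021	77194	6.0e-120	ND3	p.Ile6Thr	-
12	DG224	c	m.12315G>A	G	A	0.011	44701	2.0e-281	TRNL2	Pathogenic	-
12	DG224	c	m.12457G>A	G	A	0.012	2796	1.0e-79	ND5	p.Ala41Thr	-
12	DG224	c	m.16182A>C	C	A	0.155	2721	4.0e-133	Dloop	-	0.065
12	DG225	m	m.16182A>C	C	A	0.188	2299	4.0e-86	Dloop	-	0.065
13	DG231	c	m.4136A>G	A	G	0.191	34006	1.0e-03	ND1	p.Tyr277Cys	0.001
13	DG232	m	m.4136A>G	A	G	0.159	38779	3.0e-04	ND1	p.Tyr277Cys	0.001
15	DG243	m	m.15431G>A	G	A	0.018	38994	2.0e-23	CYTB	p.Ala229Thr	0.018
17	DG249	c	m.9941A>G	A	G	0.02	79897	2.0e-104	COX3	p.Val245=	0.001
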