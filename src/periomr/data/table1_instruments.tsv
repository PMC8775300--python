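snp_id	effect_allele	other_allele	eaf	beta	se	pvalue	n	gene
rs72694438	a	NA	0.21	0.021	0.0033	2.25e-10	487823	AMY1C
rs4971099	a	NA	0.55	-0.021	0.0027	7.47e-15	487823	KRTCAP2
rs2046850	t	NA	0.19	-0.019	0.0033	1.77e-8	487823	SYT14
rs3820640	t	NA	0.84	0.020	0.0037	2.65e-8	487823	ITPKB
rs2652452	a	NA	0.45	-0.016	0.0027	3.27e-9	487823	KCNJ3
rs263771	a	NA	0.23	0.018	0.0031	6.53e-9	487823	ZNF804A
rs121908120	a	NA	0.03	-0.081	0.0083	2.03e-22	487823	WNT10A
rs11676272	a	NA	0.52	-0.015	0.0026	1.07e-8	487823	ADCY3
rs80270335	t	NA	0.09	0.027	0.0045	2.1e-9	487823	ALK
rs62106258	t	NA	0.95	0.042	0.0062	8.6e-12	487823	FAM150B
rs5831974	d	NA	0.45	-0.016	0.0027	6.97e-10	487823	AAK1
rs61790808	a	NA	0.64	-0.016	0.0028	9.1e-9	487823	STAG1
rs9831002	t	NA	0.49	-0.016	0.0026	8.79e-10	487823	KCNH8
rs185566659	a	NA	0.032	0.045	0.0075	1.54e-9	487823	OPA1
rs7429279	a	NA	0.41	0.016	0.0027	1.28e-9	487823	RARB
3:50135699DI	d	NA	0.48	-0.018	0.0027	4.79e-12	487823	RBM5
rs1352724	a	NA	0.22	-0.018	0.0032	3.64e-8	487823	EFNA5
rs1122171	t	NA	0.59	0.044	0.0027	2.84e-62	487823	C5orf66
rs55769264	a	NA	0.45	0.015	0.0027	2.84e-8	487823	CDH9
rs1482698	c	NA	0.38	0.020	0.0027	1.47e-13	487823	FGF10
rs9366651	t	NA	0.51	-0.029	0.0026	2.66e-28	487823	HLA
rs898797	t	NA	0.59	0.015	0.0027	1.52e-8	487823	LOC157273
rs10987008	a	NA	0.64	0.021	0.0028	7.47e-14	487823	PBX3
rs10811723	a	NA	0.30	-0.019	0.0029	3.41e-11	487823	DMRTA1
rs7852129	a	NA	0.89	-0.025	0.0038	7.91e-11	487823	PRUNE2
rs7918807	t	NA	0.52	0.015	0.0027	3.58e-8	487823	STFA1P
rs149467613	a	NA	0.05	-0.034	0.0062	3.21e-8	487823	P2RY2
rs10772314	a	NA	0.40	-0.015	0.0027	3.16e-8	487823	KLRAP1
rs72748935	t	NA	0.46	-0.028	0.0027	1.31e-26	487823	CA12
rs6495046	c	NA	0.36	-0.017	0.0028	3.47e-10	487823	NEO1
rs10851907	a	NA	0.41	0.016	0.0027	1.03e-9	487823	CHRNA3
rs2072693	t	NA	0.48	0.014	0.0026	4.92e-8	487823	RHCG
rs8054556	a	NA	0.46	0.016	0.0027	2.23e-9	487823	TMEM219
rs1108343	t	NA	0.36	0.016	0.0028	1.32e-8	487823	SALL1
rs10048146	a	NA	0.81	-0.026	0.0034	5.2e-14	487823	FOXL1
rs3865314	a	NA	0.51	0.015	0.0026	1.48e-8	487823	NPEPPS
rs9905793	a	NA	0.091	0.027	0.0046	6.51e-9	487823	HOXB-AS2
rs34559440	t	NA	0.68	-0.016	0.0028	1.14e-8	487823	KCNJ2
rs7217268	a	NA	0.38	0.016	0.0027	1.48e-9	487823	LOC100499467
rs57067187	t	NA	0.63	0.015	0.0027	6.9e-9	487823	BAHCC1
rs28822480	a	NA	0.29	0.021	0.0029	7.08e-13	487823	MC4R
rs2238651	t	NA	0.24	0.017	0.0031	4.39e-8	487823	CRLF1
rs11672900	a	NA	0.47	-0.020	0.0027	4.67e-14	487823	MAMSTR
rs4816017	a	NA	0.29	-0.017	0.0029	7.08e-9	487823	HAO1
rs140357883	d	NA	0.84	0.022	0.0036	2.33e-9	487823	MTMR3
rs1569414	t	NA	0.73	-0.020	0.0030	1.19e-11	487823	FAM118A
rs5922945	t	NA	0.34	-0.016	0.0028	1.55e-8	487823	HDX
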