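snp	gene	coded_allele	EA_caf	EA_beta	EA_se	EA_p	AA_caf	AA_beta	AA_se	AA_p	AI_caf	AI_beta	AI_se	AI_p	MAH_caf	MAH_beta	MAH_se	MAH_p	generalized
rs2144300	GALNT2	T	0.60	0.59	0.14	3.33E-05	0.15	0.48	0.31	0.12	0.55	0.29	0.25	0.25	0.56	0.39	0.34	0.25	N
rs17145738	MLXIPL	T	0.12	0.91	0.21	1.64E-05	0.09	-0.28	0.40	0.46	0.08	0.46	0.48	0.34	0.07	0.25	0.67	0.71	N
rs328	LPL	C	0.90	-2.29	0.24	5.60E-22	0.93	-1.79	0.52	5.84E-04	0.97	-1.55	0.85	0.07	0.94	-2.31	0.69	8.80E-04	N
rs2197089	LPL	T	0.55	0.90	0.13	9.49E-11	0.78	0.95	0.27	4.79E-04	0.40	1.10	0.26	2.19E-05	0.47	1.22	0.33	2.56E-04	Y
rs6586891	LPL	A	0.66	0.96	0.14	5.88E-11	0.84	0.60	0.30	4.76E-02	0.44	0.76	0.26	2.86E-03	0.53	1.27	0.34	1.73E-04	Y
rs471364	TTC39B	A	0.89	0.35	0.23	0.13	0.81	0.24	0.31	0.45	0.97	0.43	0.77	0.58	0.92	-0.23	0.69	0.74	N
rs4149268	ABCA1	A	0.37	-0.30	0.18	0.12	0.67	-0.03	0.35	0.92	NA	NA	NA	NA	0.32	-0.17	0.40	0.67	N
rs3890182	ABCA1	A	0.12	-1.06	0.20	4.53E-07	0.12	-0.83	0.34	1.39E-02	0.05	-0.92	0.72	0.20	0.09	-0.24	0.63	0.70	N
rs1883025	ABCA1	A	0.26	-0.44	0.38	0.25	0.34	0.02	0.56	0.97	NA	NA	NA	NA	0.27	-0.59	0.44	0.18	N
rs174547	FADS1	T	0.66	0.84	0.17	1.14E-06	0.91	0.94	0.42	2.73E-02	0.21	0.56	0.41	0.17	0.39	1.17	0.38	1.98E-03	N
rs28927680	APOA1/C3/A4/A5	G	0.93	1.51	0.26	8.61E-09	0.84	-0.03	0.30	0.93	0.83	1.19	0.37	1.13E-03	0.86	1.00	0.48	3.98E-02	N
rs964184	APOA1/C3/A4/A5	C	0.86	1.57	0.25	6.08E-10	0.80	0.48	0.39	0.22	0.78	1.32	2.48	0.60	0.71	1.98	0.38	1.55E-07	N
rs3135506	APOA1/C3/A4/A5	C	0.06	-1.86	0.31	1.42E-09	0.06	-1.94	0.60	1.17E-03	0.17	-1.41	0.37	1.40E-04	0.14	-1.22	0.54	2.45E-02	Y
rs2338104	MMAB-MVK	C	0.46	-0.40	0.14	5.64E-03	0.27	-0.35	0.27	0.19	0.58	-0.03	0.26	0.91	0.52	-0.92	0.38	1.46E-02	N
rs4775041	LIPC	C	0.29	1.31	0.16	1.03E-16	0.14	0.79	0.35	2.55E-02	0.21	1.34	0.47	2.05E-05	0.18	1.34	0.47	4.66E-03	Y
rs261332	LIPC	A	0.20	1.76	0.24	1.99E-13	0.24	0.31	0.43	0.46	NA	NA	NA	NA	0.15	0.66	0.72	0.35	N
rs1864163	CETP	A	0.23	-2.07	1.36	0.13	0.27	-2.79	1.02	6.19E-03	NA	NA	NA	NA	0.28	-2.98	1.26	1.78E-02	N
rs12596776	CETP	C	0.90	-1.36	0.31	1.18E-05	0.94	-0.48	0.70	0.50	NA	NA	NA	NA	0.94	-0.13	0.75	0.86	N
rs9989419	CETP	A	0.39	-2.17	0.14	1.71E-53	0.59	0.02	0.24	0.93	0.26	-1.62	0.30	4.42E-08	0.32	-2.29	0.39	5.29E-09	N
rs3764261	CETP	T	0.32	3.64	0.15	8.83E-129	0.32	2.79	0.25	5.98E-28	0.31	2.81	0.27	5.00E-25	0.33	2.68	0.40	2.53E-11	Y
rs1566439	CETP	A	0.60	-0.54	0.16	1.07E-03	0.78	0.16	0.37	0.67	NA	NA	NA	NA	0.53	-0.42	0.37	0.25	N
rs2271293	LCAT	A	0.12	1.45	0.22	8.40E-11	0.68	1.11	0.43	1.05E-02	0.26	1.26	0.29	1.65E-05	0.14	0.99	0.52	5.65E-02	N
rs2156552	LIPG	T	0.17	-1.27	0.19	5.11E-11	0.04	-0.59	0.62	0.34	0.05	-0.96	0.69	0.17	0.08	-0.49	0.68	0.47	N
rs2967605	ANGPTL4	A	0.18	-0.90	0.18	1.12E-06	0.21	-0.89	0.29	2.24E-03	0.30	-0.26	0.28	0.35	0.23	-0.67	0.43	0.12	N
rs4420638	APOE/C1/C4	A	0.82	1.00	0.20	5.69E-07	0.80	-1.01	0.35	4.29E-03	0.90	1.38	0.48	3.95E-03	0.90	1.45	0.59	1.47E-02	N
rs1800961	HNF4A	T	0.03	-1.14	0.41	5.78E-03	0.01	-1.01	1.46	0.49	0.03	-1.43	0.73	0.05	0.04	-2.33	0.95	1.42E-02	N
rs7679	PLTP	T	0.82	0.95	0.21	8.42E-06	0.96	0.01	0.58	0.99	0.94	0.31	0.58	0.60	0.89	0.89	0.60	0.14	N
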