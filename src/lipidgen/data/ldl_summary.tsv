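snp	gene	coded_allele	EA_caf	EA_beta	EA_se	EA_p	AA_caf	AA_beta	AA_se	AA_p	AI_caf	AI_beta	AI_se	AI_p	MAH_caf	MAH_beta	MAH_se	MAH_p	generalized
rs11206510	PCSK9	T	0.81	1.98	0.45	1.44E-05	0.86	0.09	0.84	0.91	0.93	-0.07	1.30	0.96	0.88	3.36	1.44	1.97E-02	N
rs11591147	PCSK9	T	0.02	-16.92	1.42	1.00E-32	4.10E-03	-22.64	5.21	1.41E-05	0.01	-15.66	4.92	1.44E-03	0.01	-23.39	5.34	1.19E-05	Y
rs646776	CELSR2/PSRC1/SORT1	A	0.78	5.74	0.44	1.44E-37	0.65	4.46	0.63	1.48E-12	NA	NA	NA	NA	0.81	7.70	1.41	4.49E-08	Y
rs599839	CELSR2/PSRC1/SORT1	A	0.77	5.67	0.45	3.61E-36	0.28	1.60	0.72	2.67E-02	0.78	6.17	0.67	3.94E-20	0.78	8.68	1.75	6.99E-07	Y
rs693	APOB	T	0.50	3.45	0.36	3.38E-21	0.24	1.60	0.69	2.04E-02	0.34	4.02	0.59	7.08E-12	0.38	1.38	1.02	0.18	N
rs562338	APOB	T	0.19	-5.52	0.45	1.05E-33	0.59	-2.54	0.59	1.57E-05	0.09	-5.44	1.05	1.93E-07	0.16	-3.90	1.33	3.42E-03	Y
rs754523	APOB	T	0.68	-3.64	0.40	3.44E-19	0.78	-2.12	0.76	5.52E-03	0.66	-4.26	0.61	2.17E-12	0.72	-1.63	1.23	0.19	N
rs6544713	ABCG8	T	0.31	2.98	0.42	1.17E-12	0.17	1.49	0.74	4.45E-02	0.11	4.76	1.10	1.51E-05	0.18	0.06	1.22	0.96	N
rs12654264	HMGCR	A	0.62	-2.66	0.37	6.56E-13	0.67	-2.02	0.61	9.39E-04	0.58	-1.17	0.59	4.55E-02	0.62	-2.06	1.04	4.68E-02	Y
rs1501908	TIMD4	G	0.64	1.23	0.44	4.961E-03	0.37	1.31	0.64	4.18E-02	0.85	-2.18	0.89	1.46E-02	0.76	2.40	1.28	6.19E-02	N
rs2650000	HNF1A	T	0.35	1.20	0.39	2.338E-03	0.12	0.15	0.97	0.88	0.41	0.73	0.57	0.20	0.37	2.58	1.17	2.84E-02	N
rs6511720	LDLR	T	0.12	-7.32	0.52	2.99E-44	0.13	-8.10	0.80	7.05E-24	0.07	-2.48	1.41	0.08	0.09	-6.43	1.62	7.34E-05	N
rs2228671	LDLR	T	0.12	-5.83	0.97	1.96E-09	0.04	-6.62	2.94	2.43E-02	NA	NA	NA	NA	0.08	-6.14	2.03	2.53E-03	Y
rs16996148	CILP2/PBX4/NCAN	T	0.08	-2.88	0.66	1.40E-05	0.15	0.77	0.80	0.34	0.04	-0.70	1.51	0.64	0.06	-2.12	2.01	0.29	N
rs4803750	BCL3	A	0.93	5.57	0.92	1.37E-09	0.92	1.52	1.77	0.39	NA	NA	NA	NA	0.86	5.95	4.68	0.20	N
rs10402271	APOE/C1/C4	T	0.67	-2.27	0.49	3.86E-06	0.84	-1.38	1.28	0.28	NA	NA	NA	NA	0.61	2.39	3.38	0.48	N
rs4420638	APOE/C1/C4	A	0.82	-5.34	0.51	2.16E-25	0.79	0.16	0.92	0.87	0.90	-3.57	1.07	8.00E-04	0.90	-5.35	1.72	1.82E-03	N
rs2075650	TOMM40	A	0.88	-4.77	1.23	1.14E-04	0.87	-2.26	2.40	0.35	NA	NA	NA	NA	0.90	0.02	5.27	1.00	N
rs6102059	MAFB	T	0.30	-0.41	0.52	0.42	0.43	-0.77	0.88	0.38	NA	NA	NA	NA	0.29	-0.30	1.22	0.80	N
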