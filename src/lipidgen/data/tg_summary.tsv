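snp	gene	coded_allele	EA_caf	EA_beta	EA_se	EA_p	AA_caf	AA_beta	AA_se	AA_p	AI_caf	AI_beta	AI_se	AI_p	MAH_caf	MAH_beta	MAH_se	MAH_p	generalized
rs1748195	ANGPTL3	C	0.66	0.03	0.01	1.93E-07	0.35	0.01	0.01	0.19	0.61	0.16	0.07	2.44E-02	0.60	0.04	0.01	1.17E-02	N
rs1260326	GCKR	T	0.42	0.05	0.01	6.44E-13	0.16	0.05	0.02	9.98E-04	0.28	0.15	0.09	8.52E-02	0.33	0.06	0.02	1.97E-04	N
rs780094	GCKR	A	0.40	0.06	0.01	1.69E-32	0.18	0.02	0.01	2.91E-02	0.25	0.04	0.01	3.23E-03	0.33	0.06	0.02	1.13E-03	Y
rs17145738	MLXIPL	T	0.12	-0.07	0.01	5.71E-24	0.09	-0.03	0.01	2.53E-02	0.08	-0.07	0.02	2.30E-04	0.07	-0.09	0.03	7.40E-04	Y
rs328	LPL	C	0.90	0.09	0.01	4.16E-30	0.93	0.08	0.02	2.62E-08	0.97	0.09	0.03	4.83E-03	0.93	0.09	0.03	6.31E-04	Y
rs2197089	LPL	T	0.55	-0.03	0.01	4.97E-15	0.78	-0.01	0.01	7.45E-02	0.41	-0.05	0.01	2.57E-06	0.48	-0.05	0.01	4.01E-04	N
rs2954029	TRIB1	A	0.54	0.05	0.01	1.13E-04	0.68	-0.01	0.02	0.46	NA	NA	NA	NA	0.62	0.06	0.02	9.28E-04	N
rs174547	FADS1	T	0.66	-0.03	0.01	3.82E-10	0.91	-0.05	0.01	3.73E-04	0.21	-0.06	0.02	1.10E-04	0.39	-0.05	0.02	1.51E-03	Y
rs28927680	APOA1/C3/A4/A5	C	0.93	-0.12	0.01	2.88E-38	0.84	0.0005	0.01	0.95	0.83	-0.13	0.01	6.33E-19	0.86	-0.08	0.02	2.15E-05	N
rs964184	APOA1/C3/A4/A5	G	0.86	-0.14	0.01	1.91E-59	0.80	-0.02	0.01	4.87E-02	0.78	-0.17	0.07	1.43E-02	0.72	-0.14	0.02	1.04E-19	Y
rs3135506	APOA1/C3/A4/A5	C	0.06	0.13	0.01	2.59E-33	0.06	0.11	0.02	2.06E-10	0.17	0.13	0.01	4.28E-20	0.14	0.13	0.02	3.08E-08	Y
rs4775041	LIPC	C	0.29	0.01	0.01	3.15E-02	0.14	0.03	0.01	4.29E-03	0.21	0.02	0.01	5.15E-02	0.18	0.01	0.02	0.58	N
rs16996148	CILP2/PBX4/NCAN	T	0.08	-0.04	0.01	3.91E-05	0.15	0.0005	0.01	0.77	0.04	-0.07	0.03	8.86E-03	0.06	-0.06	0.03	2.69E-02	N
rs7679	PLTP	T	0.82	-0.02	0.01	2.84E-02	0.96	-0.01	0.02	0.61	0.94	-0.002	0.02	0.93	0.89	-0.03	0.03	0.31	N
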