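strain	major_type	gene	length_bp	is_reference	ct_mean	ct_sd	copies_mean	copies_sd	published_ratio
KY7-11	alpha	12S	165	0	11.50	0.17	57.17	9.81
KY7-11	alpha	COX1-ex3	121	0	11.74	0.12	65.67	9.93
KY7-11	alpha	COX1-alpha	227	0	15.80	0.36	2.15	0.59	1100
KY7-11	alpha	COX1-beta	234	0	25.98	0.66	1.95e-3	0.85e-3
KY7-11	alpha	TUB	140	1	16.55	0.19
GB192	alpha	12S	165	0	12.61	0.17	72.24	13.12
GB192	alpha	COX1-ex3	121	0	13.15	0.09	66.52	9.61
GB192	alpha	COX1-alpha	227	0	17.43	0.22	1.83	0.37	108
GB192	alpha	COX1-beta	234	0	24.21	0.40	1.68e-2	0.50e-2
GB192	alpha	TUB	140	1	17.98	0.19
XY18-9	alpha	12S	165	0	12.82	0.04	67.15	9.25
XY18-9	alpha	COX1-ex3	121	0	12.87	0.03	88.90	12.24
XY18-9	alpha	COX1-alpha	227	0	22.54	0.16	0.058	0.01	292
XY18-9	alpha	COX1-beta	234	0	30.69	0.07	1.98e-4	0.29e-4
XY18-9	alpha	TUB	140	1	18.11	0.20
KY7-21	beta	12S	165	0	10.90	0.10	65.83	9.51
KY7-21	beta	COX1-ex3	121	0	10.94	0.11	87.16	12.60
KY7-21	beta	COX1-alpha	227	0	28.13	0.37	3.12e-4	0.92e-4
KY7-21	beta	COX1-beta	234	0	13.28	0.17	8.97	1.54	28750
KY7-21	beta	TUB	140	1	16.16	0.18
JN1-13	beta	12S	165	0	12.55	0.11	83.32	6.92
JN1-13	beta	COX1-ex3	121	0	12.60	0.10	109.45	8.36
JN1-13	beta	COX1-alpha	227	0	31.73	0.23	1.02e-4	0.16e-4
JN1-13	beta	COX1-beta	234	0	16.46	0.03	3.90	0.14	38235
JN1-13	beta	TUB	140	1	18.16	0.04
SL3-13	beta	12S	165	0	11.33	0.06	150.88	7.31
SL3-13	beta	COX1-ex3	121	0	11.65	0.06	164.52	7.97
SL3-13	beta	COX1-alpha	227	0	32.55	0.17	4.49e-5	0.53e-5
SL3-13	beta	COX1-beta	234	0	14.25	0.28	14.32	2.75	318930
SL3-13	beta	TUB	140	1	17.80	0.03
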