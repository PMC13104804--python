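region	hemisphere	cn_mean	pd_mean	ad_mean	pda	ada
Brain Stem	midline	20.85	21.95	19.78	-5.25	5.15
LH Accum	LH	0.49	0.50	0.38	-2.79	21.77
LH Amyg	LH	1.67	1.72	1.14	-2.82	32.21
LH Caud	LH	3.44	3.47	3.31	-0.69	3.87
LH Cereb Cortex	LH	50.81	52.71	47.07	-3.74	7.36
LH Cereb WM	LH	14.00	14.82	13.12	-5.86	6.28
LH Ent	LH	1.75	1.82	1.15	-4.11	34.11
LH Hipp	LH	4.02	4.09	2.88	-1.88	28.36
LH Pall	LH	2.00	2.08	1.88	-4.09	6.13
LH Put	LH	4.62	4.61	4.19	0.25	9.25
LH Thal	LH	7.00	7.32	6.07	-4.56	13.30
RH Accum	RH	0.50	0.52	0.39	-3.54	21.83
RH Amyg	RH	1.78	1.88	1.26	-5.51	28.90
RH Caud	RH	3.63	3.68	3.44	-1.33	5.18
RH Cereb Cortex	RH	51.80	53.71	47.59	-3.69	8.12
RH Cereb WM	RH	13.35	14.16	12.57	-6.03	5.84
RH Ent	RH	1.72	1.76	1.12	-2.35	35.16
RH Hipp	RH	4.09	4.22	2.99	-3.13	26.82
RH Pall	RH	1.91	2.01	1.84	-5.20	3.90
RH Put	RH	4.67	4.68	4.29	-0.23	8.15
RH Thal	RH	6.89	7.18	6.02	-4.15	12.64
LH Cau Ant Cing	LH	2.72	2.94	2.54	-8.09	6.64
LH Cau Mid Front	LH	5.63	5.89	5.01	-4.72	10.98
LH Cuneus	LH	4.12	4.27	3.72	-3.59	9.61
LH Fusiform	LH	7.47	7.79	6.18	-4.22	17.26
LH Inf Pariet	LH	10.61	11.01	9.26	-3.81	12.72
LH Inftemp	LH	10.82	11.17	8.56	-3.23	20.90
LH Insula	LH	6.39	6.61	5.57	-3.49	12.79
LH Lat Occip	LH	9.62	9.93	8.90	-3.21	7.53
LH Lat Orbitofront	LH	4.79	5.04	4.36	-5.18	9.06
LH Med Orbitofront	LH	4.09	4.27	3.73	-4.42	8.77
LH Midtemp	LH	11.60	12.15	9.34	-4.73	19.49
LH Paracen	LH	3.46	3.61	3.17	-4.36	8.38
LH Parahipp	LH	2.65	2.77	2.04	-4.46	23.11
LH Pars Orbit	LH	1.81	1.92	1.71	-5.88	5.30
LH Pars Operc	LH	3.41	3.55	3.08	-4.18	9.64
LH Pars Triang	LH	3.44	3.62	3.31	-5.14	3.79
LH Pericalc	LH	1.78	1.84	1.62	-3.35	8.79
LH Poscen	LH	9.33	9.70	8.63	-4.03	7.51
LH Post Cing	LH	3.00	3.14	2.64	-4.59	12.07
LH Precen	LH	10.15	10.53	9.38	-3.76	7.59
LH Precun	LH	8.20	8.87	6.91	-8.23	15.70
LH Rost Ant Cing	LH	2.47	2.64	2.21	-6.69	10.61
LH Rost Mid Front	LH	14.52	15.16	12.98	-4.42	10.64
LH Sup Front	LH	14.02	14.62	12.64	-4.31	9.82
LH Sup Pariet	LH	8.83	9.21	7.80	-4.29	11.69
LH Sup Temp	LH	8.79	9.19	7.65	-4.56	12.93
LH Supramarg	LH	7.40	7.70	6.54	-4.01	11.61
LH Transv Temp	LH	1.68	1.75	1.48	-4.11	11.74
RH Cau Ant Cing	RH	2.57	2.75	2.36	-7.01	8.23
RH Cau Mid Front	RH	5.14	5.38	4.59	-4.72	10.68
RH Cuneus	RH	4.03	4.17	3.65	-3.53	9.49
RH Fusiform	RH	7.66	7.96	6.32	-3.94	17.47
RH Inf Pariet	RH	10.39	10.81	9.20	-4.07	11.44
RH Inftemp	RH	10.90	11.27	8.62	-3.39	20.88
RH Insula	RH	6.28	6.51	5.44	-3.64	13.43
RH Lat Occip	RH	9.48	9.79	8.70	-3.29	8.21
RH Lat Orbitofront	RH	4.83	5.06	4.38	-4.76	9.34
RH Med Orbitofront	RH	4.11	4.28	3.75	-4.07	8.68
RH Midtemp	RH	11.73	12.52	9.71	-6.72	17.21
RH Paracen	RH	3.35	3.48	3.10	-3.88	7.50
RH Parahipp	RH	2.67	2.80	2.09	-4.71	21.79
RH Pars Operc	RH	3.38	3.52	3.06	-4.04	9.43
RH Pars Orbit	RH	1.86	2.01	1.83	-7.83	1.63
RH Pars Triang	RH	3.39	3.47	3.16	-2.29	6.86
RH Pericalc	RH	1.72	1.77	1.56	-2.94	9.30
RH Poscen	RH	8.65	8.93	8.03	-3.18	7.22
RH Post Cing	RH	3.08	3.23	2.69	-4.90	12.71
RH Precen	RH	10.26	10.63	9.45	-3.63	7.86
RH Precun	RH	8.85	9.50	7.57	-7.35	14.40
RH Rost Ant Cing	RH	2.52	2.66	2.23	-5.42	11.47
RH Rost Mid Front	RH	14.01	14.56	12.56	-3.92	10.36
RH Sup Front	RH	13.62	14.16	12.25	-3.96	10.05
RH Sup Pariet	RH	8.69	9.03	7.72	-3.95	11.16
RH Sup Temp	RH	8.91	9.29	7.70	-4.28	13.55
RH Supramarg	RH	7.23	7.51	6.39	-3.88	11.63
RH Transv Temp	RH	1.65	1.71	1.46	-3.88	11.52
CSF	global	1.15	1.31	1.54	-14.38	-34.07
LH Cerebr White Mat	LH	221.23	232.12	199.60	-4.92	9.78
LH Chor Plex	LH	0.79	0.87	1.00	-10.40	-26.08
LH Lat Vent	LH	13.28	15.72	24.93	-18.37	-87.78
RH Cerebr White Mat	RH	221.08	232.29	200.39	-5.07	9.36
RH Chor Plex	RH	0.86	0.93	1.02	-7.69	-18.17
RH Lat Vent	RH	11.97	14.09	22.18	-17.72	-85.28
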