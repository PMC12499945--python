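case	n_conventional	third_phase	eqd2_sg_fr	u_sg_fr	eqd2_c_fr	u_c_fr	delta_fr	u_delta_fr	eqd2_sg_total	u_sg_total	eqd2_c_total	u_c_total	delta_total	u_delta_total
1	9	0	8.7	0.2	3.38	0.08	157	9	39.1	0.8	33.8	0.8	15.7	3.6
2	9	0	8.4	0.2	3.37	0.08	149	8	38.7	0.8	33.7	0.8	14.9	3.6
3	9	0	7.7	0.2	3.27	0.08	135	8	37.1	0.7	32.7	0.8	13.5	3.6
4	19	1	6.1	0.1	2.31	0.06	162	9	50.0	1.1	46.2	1.1	8.1	3.6
5	9	0	5.6	0.1	3.24	0.08	73	6	34.8	0.7	32.4	0.8	7.3	3.4
6	19	1	5.0	0.1	2.35	0.06	115	7	49.7	1.1	47.0	1.2	5.7	3.6
7	9	0	8.6	0.2	3.16	0.08	173	11	37.1	0.9	31.6	1.0	17.3	4.7
8	19	0	4.8	0.1	2.05	0.05	134	8	43.7	1.0	41.0	1.0	6.7	3.6
9	12	0	5.0	0.1	2.30	0.06	116	7	32.5	0.7	29.8	0.7	8.9	3.6
10	19	0	3.22	0.08	2.00	0.05	61	6	41.2	1.0	40	1.0	3.1	3.5
11	8	0	4.3	0.1	3.23	0.08	34	5	30.2	0.6	29	0.7	3.8	3.3
12	14	1	4.2	0.1	2.30	0.06	83	6	36.4	0.8	34.5	0.9	5.5	3.7
13	19	1	2.63	0.06	2.30	0.06	14	4	46.3	1.1	46.0	1.2	0.7	3.5
14	4	0	7.5	0.2	6.2	0.2	20	4	32.4	0.6	31.2	0.8	3.9	3.2
15	19	0	2.8	0.1	2.30	0.06	20	4	46.5	1.1	46.0	1.2	1.0	3.6
16	4	0	8.2	0.2	6.5	0.2	26	4	34.1	0.6	32.4	0.8	5.3	3.1
17	19	0	7.6	0.2	2.30	0.06	230	12	51.3	1.2	46.0	1.2	11.5	3.8
18	9	0	8.2	0.2	3.25	0.08	151	8	37.4	0.7	32.5	0.8	15.1	3.6
19	9	0	6.8	0.2	3.24	0.08	110	7	36.0	0.7	32.4	0.8	11.0	3.5
20	19	0	4.3	0.1	2.30	0.06	88	7	48.0	1.1	46.0	1.2	4.4	3.7
21	27	1	5.3	0.1	1.77	0.05	200	11	53.1	1.4	49.6	1.4	7.1	4.1
22	19	0	4.7	0.1	2.30	0.06	106	7	48.4	1.1	46.0	1.2	5.3	3.7
23	9	0	7.5	0.2	3.25	0.08	131	8	36.7	0.7	32.5	0.8	13.0	3.6
24	19	1	6.7	0.2	2.30	0.06	190	10	50.4	1.2	46.0	1.2	9.5	3.8
25	19	1	3.58	0.09	2.30	0.06	56	6	47.3	1.1	46.0	1.2	2.8	3.7
26	9	0	6.1	0.1	3.25	0.08	89	6	35.4	0.7	32.5	0.8	8.9	3.5
27	9	0	6.6	0.2	3.25	0.08	104	7	35.9	0.7	32.5	0.8	10.4	3.5
28	19	1	4.2	0.1	2.30	0.06	84	7	47.9	1.1	46.0	1.2	4.2	3.7
29	9	0	4.9	0.1	3.25	0.08	52	5	34.2	0.7	32.5	0.8	5.2	3.4
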