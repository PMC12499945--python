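case	site	origin	histology	concurrent_chemo	initial_gtv_cc	outer_dose_gy	intermediate_dose_gy	inner_dose_gy	followup_months	symptom_response	radiologic_response	pct_volume_reduction	residual_volume_cc
1	Right cheek mucosa	metastasis	Squamous	N	100	3	9	12	6	C	C	100	0
2	Pelvis	metastasis	NA	N	809	3	9	12	3	P	S	0	780
3	Sternum	metastasis	Plasmacytoma	N	786	3	9	12	1	P	P	40	470
4	Lung (LLL)	primary	Squamous	N	48	2.25	9	11.25	27	none	C	100	0
5	Left supraclavicular lymph node	metastasis	Adenocarcinoma	N	87	3	9	12	4	P	P	54	40
6	Lung (RUL)	primary	Squamous	Y	189	2.25	9	12	27	none	P	80	37
7	Lung (RLL)	primary	NA	N	104	3	9	12	10	none	S	0	100
8	Lung (LUL)	primary	Adenocarcinoma	Y	192	2	9	12	0	P	NA	NA	NA
9	Right cervical lymph node	metastasis	Squamous	N	48	2.75	6	12	21	P	C	100	0
10	Right iliac bone	metastasis	Plasmacytoma	N	876	2	4	6	15	C	C	100	0
11	Right Vastus Intermedius muscle	metastasis	Large-cell	N	1500	3	6	NA	29	C	C	100	0
12	Left cervical lymph node	metastasis	Adenocarcinoma	N	135	2.25	6	10	5	C	C	100	0
13	Lung (RUL)	primary	Adenocarcinoma	Y	269	3	9	12	21	C	P	74	70
14	Left scapula	metastasis	Hepatocarcinoma	N	91	5	8	12	4	C	P	70	27
15	Lung (LUL)	primary	Adenocarcinoma	N	71	2.25	6	NA	9	P	P	55	32
16	Left supraclavicular lymph node	metastasis	Hepatocarcinoma	N	101	5	9	12	0	NA	NA	NA	NA
17	Lung (LLL)	primary	Squamous	Y	118	2.25	8	12	11	C	C	100	0
18	Lung (LUL)	primary	Squamous	N	150	4	9	12	12	C	C	100	0
19	Left cervical lymph node	metastasis	Squamous	N	190	3	9	12	8	C	C	100	0
20	Lung (RUL)	primary	Adenocarcinoma	N	50	4	7	12	4	none	P	48	26
21	Left cervical lymph node	metastasis	Squamous	Y	295	3	9	12	1	P	S	NA	NA
22	Lung (RLL)	primary	Squamous	N	205	2.25	7	12	2	none	P	76	49
23	Vaginal vault	primary	Adenocarcinoma	N	100	3	6	12	2	C	C	100	0
24	Lung (RUL)	primary	Adenocarcinoma	N	88	4	9	12	2	P	P	62	33
25	Lung (RLL)	primary	Adenocarcinoma	Y	184	2.25	4	9	1	P	P	63	68
26	Uterus	metastasis	Sarcoma	N	215	4	6	12	1	C	P	49	110
27	Lung (RUL)	primary	Squamous	N	61	4	8	12	1	none	P	92	5
28	Lung (LLL)	primary	Adenocarcinoma	Y	73	4	9	12	0	C	P	65	25
29	Lung (LUL)	primary	Squamous	N	67	3	4	9	0	C	P	64	24
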