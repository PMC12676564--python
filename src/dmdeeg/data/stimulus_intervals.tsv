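subject_id	group	onset	offset
1	AD	3.80	73.79
2	AD	17.39	107.38
3	AD	0.03	45.49
4	AD	15.35	105.34
5	AD	5.37	94.87
6	AD	14.37	123.38
7	AD	17.39	107.39
8	AD	15.57	105.56
9	AD	21.89	111.88
10	AD	15.08	105.07
11	AD	13.99	103.98
12	AD	2.99	92.98
13	AD	17.18	107.17
14	AD	10.05	100.04
15	AD	0.45	30.45
16	AD	5.05	95.04
17	AD	19.54	109.53
18	AD	24.73	114.72
19	AD	0.68	90.67
20	AD	0.95	90.95
21	AD	18.10	108.09
22	AD	4.05	94.04
23	AD	2.92	72.91
24	AD	7.33	77.32
25	AD	3.81	73.80
26	AD	12.33	82.32
27	AD	4.97	94.96
28	AD	3.89	73.88
29	AD	34.24	104.23
30	AD	1.59	71.58
31	AD	7.27	77.26
32	AD	2.79	72.78
33	AD	25.86	95.85
34	AD	16.08	86.07
35	AD	18.33	108.32
36	AD	5.32	75.32
37	CN	6.48	76.47
38	CN	14.82	84.82
39	CN	14.94	165.01
40	CN	0.52	70.51
41	CN	19.09	109.08
42	CN	16.49	106.49
43	CN	7.25	157.78
44	CN	9.52	99.52
45	CN	1.51	126.46
46	CN	14.29	104.28
47	CN	14.33	104.33
48	CN	4.57	94.56
49	CN	27.09	117.08
50	CN	9.49	99.48
51	CN	12.25	102.24
52	CN	2.08	92.07
53	CN	10.55	100.54
54	CN	3.83	153.64
55	CN	15.39	105.38
56	CN	17.39	107.38
57	CN	0.06	69.45
58	CN	0.05	61.44
59	CN	0.45	70.44
60	CN	0.74	130.71
61	CN	6.05	76.04
62	CN	16.58	86.57
63	CN	2.74	72.73
64	CN	0.03	23.48
65	CN	0.03	20.28
66	FTD	1.26	91.25
67	FTD	16.01	106.00
68	FTD	0.30	90.29
69	FTD	14.25	104.24
70	FTD	7.11	97.10
71	FTD	3.88	93.88
72	FTD	0.95	90.94
73	FTD	18.57	108.56
74	FTD	4.23	94.22
75	FTD	12.63	122.50
76	FTD	10.85	100.67
77	FTD	8.49	98.48
78	FTD	8.11	38.10
79	FTD	14.65	84.64
80	FTD	8.56	78.55
81	FTD	21.90	91.89
82	FTD	3.81	73.80
83	FTD	1.40	71.39
84	FTD	2.29	72.28
85	FTD	29.51	99.50
86	FTD	9.77	79.76
87	FTD	5.51	75.50
88	FTD	58.40	128.39
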