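no	rt	precursor_mz	adduct	name	cas	formula	fill_percent	matrix	source	score
1	0.83	341.1081	[M-H]-	sucrose	57-50-1	C12H22O11	14.3	95EtOH	Lmatch	86
2	0.95	232.1456	[M+H]+	aminophenazone	58-15-1	C13H17N3O	9.5	95EtOH	genDB	6.2
3	1.28	124.0759	[M+H]+	o-anisidine	90-04-0	C7H9NO	14.3	3HAC	Lmatch	86
4	1.65	158.0972	[M+H]+	quinoline, 2,7-dimethyl-	93-37-8	C11H11N	28.6	3HAC	volDB	5
5	1.77	122.0967	[M+H]+	2,4-dimethylbenzenamine	95-68-1	C8H11N	42.9	3HAC	Lmatch	88
6	2.61	202.0432	[M+H]+	thiabendazole	148-79-8	C10H7N3S	9.5	extract	Lmatch	81
7	3.11	114.0915	[M+H]+	caprolactam	105-60-2	C6H11NO	23.8	3HAC	Lmatch	86
8	3.46	195.0885	[M+H]+	caffeine	58-08-2	C8H10N4O2	47.6	extract	Lmatch	87
9	3.92	142.0427	[M+H]+	3-chloro-o-toluidine	87-60-5	C7H8ClN	14.3	3HAC	cppDB	5.4
10	4.78	274.2754	[M+H]+	N,N-bis(2-hydroxyethyl)dodecylamine	1541-67-9	C16H35NO2	61.9	3HAC	Lmatch	97
11	4.83	214.2535	[M+H]+	N,N-dimethyldodecylamine	112-18-5	C14H31N	100	3HAC	cppDB	6.2
12	4.83	200.2371	[M+H]+	N-methyldodecylamine	7311-30-0	C13H29N	90.5	extract	Lmatch	87
13	4.90	285.2917	[M+H]+	N-[3-(dimethylamino)propyl]dodecanamide	3179-80-4	C17H36N2O	33.3	3HAC	Lmatch	72
14	5.02	230.2482	[M+H]+	lauramine oxide	1643-20-5	C14H31NO	33.3	extract	Lmatch	92
15	5.02	150.0912	[M+H]+	N-(2,4-dimethylphenyl)formamide	60397-77-5	C9H11NO	14.3	extract	Lmatch	84
16	5.04	288.2896	[M+H]+	2-aminoheptadecane-1,3-diol		C17H37NO2	14.3	extract	Lmatch	87
17	5.33	202.0854	[M+H]+	simazine	122-34-9	C7H12ClN5	19	extract	Lmatch	90
18	5.34	242.2852	[M+H]+	N,N-dimethyltetradecylamine	112-75-4	C16H35N	100	95EtOH	Lmatch	86
19	5.40	266.0975	[M+H]+	albendazole	54965-21-8	C12H15N3O2S	9.5	extract	Lmatch	80
20	5.70	200.1191	[M+H]+	pyrimethanil	53112-28-0	C12H13N3	28.6	3HAC	Lmatch	92
21	5.74	242.1439	[M+H]+	prometryn	7287-19-6	C10H19N5S	9.5	extract	Lmatch	88
22	5.79	242.1435	[M+H]+	terbutryn	886-50-0	C10H19N5S	9.5	extract	Lmatch	78
23	5.86	192.1384	[M+H]+	diethyltoluamide	134-62-3	C12H17NO	61.9	95EtOH	Lmatch	93
24	5.88	270.3173	[M+H]+	N,N-dimethylhexadecylamine	112-69-6	C18H39N	95.2	95EtOH
25	5.95	312.3632	[M+H]+	N-methyldidecylamine	7396-58-9	C21H45N	42.9	95EtOH	Lmatch	92
26	6.14	404.1255	[M+H]+	azoxystrobin	131860-33-8	C22H17N3O5	9.5	extract	Lmatch	89
27	6.18	253.0307	[M+H]+	3,3'-dichlorobenzidine	91-94-1	C12H10Cl2N2	14.3	95EtOH	Lmatch	84
28	6.37	230.1168	[M+H]+	sebuthylazine	7286-69-3	C9H16ClN5	28.6	extract	Lmatch	87
29	6.43	215.9981	[M-H]-	propanil	709-98-8	C9H9Cl2NO	9.5	95EtOH	Lmatch	90
30	6.43	182.0097	[M+H]+	2-(methylsulfanyl)-1,3-benzothiazole	615-22-5	C8H7NS2	9.5	extract	Lmatch	81
31	6.48	194.1175	[M+H]+	ethyl 4-(dimethylamino)benzoate	10287-53-3	C11H15NO2	28.6	extract	Lmatch	91
32	6.71	332.0665	[M+H]+	piroxicam	36322-90-4	C15H13N3O4S	9.5	3HAC	genDB	5.9
33	6.75	284.1428	[M+H]+	metolachlor	51218-45-2	C15H22ClNO2	9.5	extract	Lmatch	86
34	6.76	415.2133	[M+H]+	dimethyldibenzylidene sorbitol	135861-56-2	C24H30O6	23.8	extract	Lmatch	64
35	6.83	293.1735	[M-H]-	3-(3,5-di-tert-butyl-1-hydroxy-4-oxocyclohexa-2,5-dien-1-yl)propanoic acid		C17H26O4	100	3HAC	cppDB	6.4
36	6.86	229.0862	[M+H]+	oxybenzone	131-57-7	C14H12O3	33.3	extract	Lmatch	85
37	6.91	198.1856	[M+H]+	1-octylpyrrolidin-2-one	2687-94-7	C12H23NO	23.8	95EtOH	cppDB	5.9
38	6.94	308.1541	[M+H]+	tebuconazole	80443-41-0	C16H22ClN3O	9.5	95EtOH	Lmatch	83
39	6.97	305.1081	[M+H]+	diazinon	333-41-5	C12H21N2O3PS	9.5	extract	Lmatch	86
40	7.00	342.078	[M+H]+	propiconazole	60207-90-1	C15H17Cl2N3O2	9.5	95EtOH	Lmatch	81
41	7.06	277.1817	[M+H]+	7,9-di-tert-butyl-1-oxaspiro(4,5)deca-6,9-diene-2,8-dione	82304-66-3	C17H24O3	47.6	95EtOH	Lmatch	83
42	7.14	406.074	[M+H]+	difenoconazole	119446-68-3	C19H17Cl2N3O3	9.5	extract	Lmatch	85
43	7.19	200.202	[M+H]+	lauramide	1120-16-7	C12H25NO	9.5	95EtOH	Lmatch	85
44	7.20	310.2367	[M+Na]+	lauric acid diethanolamide	120-40-1	C16H33NO3	14.3	95EtOH	Lmatch	86
45	7.22	395.0808	[M+H]+	diflufenican	83164-33-4	C19H11F5N2O2	9.5	95EtOH	genDB	6.3
46	7.24	220.1125	[M+H]+	N-phenyl-2-naphthylamine	135-88-6	C16H13N	9.5	95EtOH	volDB	5.4
47	7.30	383.2042	[M+Na]+	tributyl citrate	77-94-1	C18H32O7	85.7	95EtOH	cppDB	6.3
48	7.32	421.2326	[M+Na]+	tris(2-butoxyethyl) phosphate	78-51-3	C18H39O7P	42.9	extract	Lmatch	89
49	7.37	277.1812	[M-H]-	3-(3,5-di-tert-butyl-4-hydroxyphenyl)propionic acid	20170-32-5	C17H26O3	28.6	extract	Lmatch	88
50	7.40	273.1853	[M+H]+	galaxolidone		C18H24O2	28.6	extract	Lmatch	83
51	7.47	179.0701	[M+H]+	3-methoxycinnamic acid	6099-04-3	C10H10O3	33.3	extract	Lmatch	86
52	7.48	599.1155	[M+Na]+	ethylene terephthalate cyclic trimer		C30H24O12	9.5	95EtOH	cppDB	5.5
53	7.54	322.1454	[M+H]+	pyriproxyfen	95737-68-1	C20H19NO3	14.3	extract	Lmatch	84
54	7.54	425.2149	[M+Na]+	tributyl acetylcitrate	77-90-7	C20H34O8	81	95EtOH	Lmatch	81
55	7.55	199.1328	[M+H-H2O]+	sebacic acid monomethyl ester	818-88-2	C11H20O4	19	extract	Lmatch	80
56	7.63	255.1746	[M+H]+	4-methylbenzylidene camphor	36861-47-9	C18H22O	38.1	extract	Lmatch	84
57	7.67	295.2272	[M-H]-	9-hydroxy-10,12-octadecadienoic acid	10075-11-3	C18H32O3	76.2	extract	Lmatch	88
58	7.77	507.2737	[M+Na]+	1,2,3-trideoxy-4,6:5,7-bis-o-[(4-propylphenyl)methylene]-nonitol (NX8000)	882073-43-0	C29H40O6	33.3	extract	Lmatch	82
59	7.88	384.1934	[M+Na]+	octocrylene	6197-30-4	C24H27NO2	100	95EtOH	Lmatch	90
60	8.00	259.2065	[M+H]+	galaxolide 1	1222-05-5	C18H26O	28.6	95EtOH	volDB	5.8
61	8.04	311.1645	[M+H]+	avobenzone	70356-09-1	C20H22O3	100	95EtOH	Lmatch	91
62	8.06	291.1998	[M+H]+	2-ethylhexyl 4-methoxycinnamate	83834-59-7	C18H26O3	61.9	extract	Lmatch	83
63	8.13	443.3351	[M+H]+	1,2,3-propanetriol 1-stearate 2,3-bisacetate	33599-07-4	C25H46O6	100	95EtOH	cppDB	6
64	8.20	256.2647	[M+H]+	palmitamide	629-54-9	C16H33NO	42.9	extract	Lmatch	85
65	8.47	381.298	[M+Na]+	2-stearoylglycerol	621-61-4	C21H42O4	76.2	95EtOH	Lmatch	92
66	8.50	327.1963	[M+H]+	Chimassorb 81	1843-05-6	C21H26O3	42.9	95EtOH	Lmatch	88
67	8.52	437.3062	[M-H]-	2,4-di-tert-butylphenyl 3,5-di-tert-butyl-4-hydroxybenzoate (UV 120)	4221-80-1	C29H42O3	9.5	95EtOH	cppDB	5.7
68	8.57	803.5445	[2M+Na]+	dioctyl phthalate	117-84-0	C24H38O4	19	95EtOH	Lmatch	88
69	8.63	393.2969	[M+Na]+	bis(2-ethylhexyl) adipate	103-23-1	C22H42O4	66.7	95EtOH	Lmatch	93
70	8.81	255.2318	[M-H]-	palmitic acid	57-10-3	C16H32O2	71.4	95EtOH	Lmatch	91
71	8.81	360.324	[M+Na]+	erucamide	112-84-5	C22H43NO	61.9	95EtOH	Lmatch	85
72	8.86	647.4585	[M+H]+	Irgafos 168	31570-04-4	C42H63O3P	100	95EtOH	Lmatch	85
73	8.86	281.2475	[M-H]-	oleic acid	112-80-1	C18H34O2	100	95EtOH	Lmatch	85
74	9.18	340.3574	[M+H]+	docosanamide	3061-75-4	C22H45NO	61.9	95EtOH	cppDB	5.9
75	9.25	469.3289	[M+Na]+	diisodecyl phthalate	89-16-7	C28H46O4	33.3	95EtOH	Lmatch	86
76	9.36	1175.776	[M-H]-	Irganox 1010	6683-19-8	C73H108O12	100	95EtOH	Lmatch	89
77	9.39	431.1784	[M+H]+	2,5-bis(5-tert-butyl-benzoxazol-2-yl)thiophene	7128-64-5	C26H26N2O2S	71.4	95EtOH	Lmatch	86
78	9.61	199.0157	[M-H]-	(4-chloro-2-methylphenoxy)acetic acid	94-74-6	C9H9ClO3	9.5	3HAC	Lmatch	73
79	10.24	663.454	[M+H]+	oxidized Irgafos 168	95906-11-9	C42H63O4P	100	95EtOH	Lmatch	98
80	10.27	385.3471	[M+H]+	(+)-4-cholesten-3-one	601-57-0	C27H44O	90.5	extract	Lmatch	71
81	11.44	553.4598	[M+Na]+	Irganox 1076	2082-79-3	C35H62O3	100	95EtOH	Lmatch	85
82	11.60	591.4948	[M+Na]+	glycerol dihexanoate	502-52-3	C35H68O5	14.3	95EtOH	Lmatch	69
83	11.73	533.529	[M+H]+	(Z)-octadec-9-enyl oleate	3687-45-4	C36H68O2	9.5	95EtOH	cppDB	5.1
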