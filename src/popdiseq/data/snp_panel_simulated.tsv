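snp_id	chromosome	position_bp	bin
1	1	4464052	NA
2	1	4918980	NA
3	1	6747184	NA
4	1	6822691	NA
5	1	7271821	NA
6	1	8098952	NA
7	1	8662055	NA
8	1	9201172	NA
9	1	10247073	NA
10	1	12041260	NA
11	1	14985200	NA
12	1	44959476	NA
13	1	67180473	NA
14	1	68864563	NA
15	1	68909790	NA
16	1	69218117	NA
17	1	70928139	NA
18	1	72494781	NA
19	1	146847931	NA
20	1	148129135	NA
21	1	149660797	NA
22	1	167602997	NA
23	1	167714661	NA
24	1	168981018	NA
25	1	204597382	NA
26	1	234385544	NA
27	1	236155502	NA
28	1	236592209	NA
29	2	0	NA
30	2	855530	NA
31	3	5524536	NA
32	3	5754583	NA
33	3	7669980	NA
34	3	14800309	NA
35	3	15194865	NA
36	3	16334091	NA
37	3	209104813	NA
38	3	210855530	NA
39	3	211377457	NA
40	3	213475311	NA
41	3	215009460	NA
42	3	216145401	NA
43	4	0	NA
44	4	34923515	NA
45	4	36303978	NA
46	4	38019829	NA
47	4	39186188	NA
48	4	148089966	NA
49	4	148380829	NA
50	5	0	NA
51	5	1575760	NA
52	5	1580048	NA
53	5	4536728	NA
54	6	146819366	NA
55	6	148468338	NA
56	6	148928894	NA
57	6	151316528	NA
58	6	152790375	NA
59	6	153651642	NA
60	6	159940903	NA
61	6	161828934	NA
62	6	162886520	NA
63	6	164783844	NA
64	6	166620102	NA
65	6	167632980	NA
66	7	0	NA
67	7	1462112	NA
68	7	14959671	NA
69	7	16157837	NA
70	7	17505219	NA
71	8	0	NA
72	8	1878784	NA
73	8	2059971	NA
74	8	86063553	NA
75	8	87675003	NA
76	8	87804291	NA
77	8	166943466	NA
78	8	167344955	NA
79	8	168464798	NA
80	8	170052048	NA
81	9	1098717	NA
82	9	2942947	NA
83	9	4581985	NA
84	9	5060295	NA
85	9	6864235	NA
86	9	7174065	NA
87	9	9114563	NA
88	9	10769264	NA
89	9	12219177	NA
90	9	85800064	NA
91	9	87218643	NA
92	9	113242081	NA
93	9	114440567	NA
94	9	116157425	NA
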