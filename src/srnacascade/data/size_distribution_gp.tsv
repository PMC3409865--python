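length	t1_unique	t1_count	t4_unique	t4_count	t10_unique	t10_count
0	1	210867	1	210867	1	210867
1	4	874	4	874	3	868
2	13	1223	5	1208	2	1195
3	19	26	0	0	0	0
4	31	77	3	44	3	44
5	75	106	3	25	1	14
6	176	407	7	196	2	168
7	438	985	29	506	8	384
8	1057	3101	55	1927	19	1743
9	1267	3474	86	2105	33	1833
10	1613	3880	109	2116	45	1765
11	2190	7228	182	4813	75	4248
12	3420	12710	348	9030	118	7765
13	5979	31843	681	25416	282	23157
14	9523	62696	1209	52573	502	48597
15	14217	92360	1678	77158	727	71842
16	20428	162361	2304	140820	963	133294
17	24845	158839	2350	132272	1037	124822
18	30838	234259	2628	201421	1129	192880
19	42079	531625	3170	486882	1428	477046
20	56585	2370690	4095	2310477	1746	2297334
21	165048	1554458	13429	1377789	5823	1335020
22	125795	593035	9028	457753	3630	427570
23	111309	192190	2952	71856	882	60608
24	419485	569003	10005	105823	1890	63240
25	10140	18330	315	7553	101	6386
26	2938	4662	97	1532	33	1182
27	0	0	0	0	0	0
28	0	0	0	0	0	0
29	0	0	0	0	0	0
30	0	0	0	0	0	0
31	0	0	0	0	0	0
32	0	0	0	0	0	0
33	0	0	0	0	0	0
34	0	0	0	0	0	0
35	0	0	0	0	0	0
36	191990	286405	4249	88532	1439	72969
total	1241503	7107714	59022	5771568	21922	5566841
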