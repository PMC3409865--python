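length	t1_unique	t1_count	t4_unique	t4_count	t10_unique	t10_count
0	1	244887	1	244887	1	244887
1	4	740	4	740	3	736
2	9	1222	2	1210	1	1203
3	8	11	0	0	0	0
4	12	17	1	5	0	0
5	29	32	0	0	0	0
6	12	13	0	0	0	0
7	19	34	1	16	1	16
8	33	47	2	12	0	0
9	75	117	5	34	1	11
10	265	603	22	329	9	263
11	888	3860	77	2912	34	2686
12	2423	10805	248	8141	81	7201
13	5025	31084	649	25642	260	23435
14	7196	49421	1126	41845	453	38029
15	8978	76421	1354	66927	556	62402
16	10078	91358	1471	80632	595	75693
17	10810	76782	1531	65399	629	60236
18	14449	123565	1932	108444	839	102136
19	23146	590427	2712	566325	1245	557986
20	34549	3427405	3449	3390972	1584	3380370
21	104213	1041397	9622	930122	4201	899662
22	71319	391368	5674	314424	2343	295743
23	54931	88444	1394	29446	438	24166
24	129638	162602	2107	21354	378	12363
25	1942	4039	77	1951	29	1669
26	542	823	18	242	7	177
27	0	0	0	0	0	0
28	0	0	0	0	0	0
29	0	0	0	0	0	0
30	0	0	0	0	0	0
31	0	0	0	0	0	0
32	0	0	0	0	0	0
33	0	0	0	0	0	0
34	0	0	0	0	0	0
35	0	0	0	0	0	0
36	188803	401327	9972	203298	3649	167962
total	669397	6818851	43451	6105309	17337	5959032
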