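energy_keV,photoelectric,incoherent,coherent,total
1,1100.3,0.025048,2.1819,1102.5
1.5596,335.1,0.045644,1.9112,337.06
1.5596,4064.8,0.045783,1.9093,4066.8
2,2261.8,0.059964,1.7219,2263.6
3,778.6,0.085171,1.3861,780.07
4,352.71,0.10333,1.1409,353.95
5,188.33,0.11696,0.95407,189.4
6,111.87,0.12743,0.80806,112.81
7,71.591,0.13557,0.69226,72.418
8,48.42,0.14196,0.5993,49.162
9,34.198,0.14701,0.52384,34.868
10,24.948,0.15102,0.46191,25.561
11,18.734,0.15424,0.41051,19.299
12,14.409,0.15684,0.36743,14.934
13,11.309,0.15893,0.33096,11.799
14,9.0298,0.16063,0.29982,9.4903
15,7.3185,0.162,0.27299,7.7534
16,6.0092,0.16311,0.24972,6.422
17,4.9911,0.164,0.22938,5.3845
18,4.188,0.16472,0.2115,4.5642
19,3.5462,0.16528,0.19568,3.9072
20,3.0275,0.16572,0.18162,3.3748
21,2.6039,0.16604,0.16906,2.939
22,2.2546,0.16628,0.15778,2.5787
23,1.9643,0.16644,0.14762,2.2783
24,1.721,0.16653,0.13842,2.0259
25,1.5157,0.16656,0.13007,1.8123
26,1.3412,0.16654,0.12247,1.6302
27,1.1921,0.16647,0.11552,1.4741
28,1.0639,0.16637,0.10916,1.3394
29,0.95311,0.16623,0.10331,1.2227
30,0.85695,0.16606,0.097924,1.1209
31,0.77309,0.16587,0.092952,1.0319
32,0.69964,0.16565,0.088352,0.95364
33,0.63505,0.16542,0.084088,0.88455
34,0.57803,0.16516,0.080127,0.82332
35,0.52752,0.16489,0.076441,0.76885
36,0.48262,0.16461,0.073004,0.72023
37,0.44258,0.16431,0.069795,0.67669
38,0.40677,0.164,0.066794,0.63757
39,0.37465,0.16368,0.063983,0.60232
40,0.34576,0.16336,0.061346,0.57046
41,0.31971,0.16302,0.05887,0.5416
42,0.29616,0.16268,0.05654,0.51538
43,0.27482,0.16234,0.054347,0.49151
44,0.25545,0.16198,0.052279,0.46971
45,0.23781,0.16163,0.050326,0.44977
46,0.22173,0.16127,0.048482,0.43148
47,0.20704,0.1609,0.046737,0.41468
48,0.19359,0.16054,0.045084,0.39921
49,0.18126,0.16017,0.043518,0.38495
50,0.16993,0.1598,0.042032,0.37176
51,0.15951,0.15942,0.040621,0.35955
52,0.1499,0.15905,0.03928,0.34823
53,0.14103,0.15867,0.038004,0.33771
54,0.13283,0.1583,0.036789,0.32792
55,0.12525,0.15792,0.035632,0.3188
56,0.11821,0.15755,0.034528,0.31029
57,0.11169,0.15717,0.033475,0.30233
58,0.10562,0.15679,0.032469,0.29488
59,0.099974,0.15641,0.031508,0.2879
60,0.094714,0.15604,0.030589,0.28134
61,0.089809,0.15566,0.02971,0.27518
62,0.08523,0.15529,0.028868,0.26938
63,0.080949,0.15491,0.028061,0.26392
64,0.076943,0.15454,0.027288,0.25877
65,0.073192,0.15417,0.026546,0.2539
66,0.069674,0.15379,0.025834,0.2493
67,0.066373,0.15342,0.02515,0.24495
68,0.063272,0.15305,0.024493,0.24082
69,0.060357,0.15269,0.023861,0.2369
70,0.057614,0.15232,0.023254,0.23319
71,0.055031,0.15195,0.022669,0.22965
72,0.052596,0.15159,0.022106,0.22629
73,0.050299,0.15123,0.021564,0.22309
74,0.048131,0.15086,0.021041,0.22004
75,0.046082,0.1505,0.020537,0.21712
76,0.044145,0.15015,0.020052,0.21434
77,0.042313,0.14979,0.019583,0.21169
78,0.040578,0.14944,0.01913,0.20914
79,0.038934,0.14908,0.018693,0.20671
80,0.037376,0.14873,0.01827,0.20438
81,0.035897,0.14838,0.017862,0.20214
82,0.034494,0.14803,0.017467,0.19999
83,0.033161,0.14769,0.017085,0.19793
84,0.031894,0.14734,0.016716,0.19595
85,0.030689,0.147,0.016358,0.19405
86,0.029542,0.14666,0.016012,0.19221
87,0.028451,0.14632,0.015677,0.19045
88,0.027411,0.14598,0.015352,0.18874
89,0.026419,0.14564,0.015037,0.1871
90,0.025474,0.14531,0.014731,0.18552
91,0.024572,0.14498,0.014435,0.18399
92,0.023711,0.14465,0.014147,0.18251
93,0.022889,0.14432,0.013868,0.18108
94,0.022104,0.14399,0.013598,0.17969
95,0.021353,0.14367,0.013335,0.17835
96,0.020634,0.14334,0.013079,0.17706
97,0.019947,0.14302,0.012831,0.1758
98,0.019289,0.1427,0.01259,0.17458
99,0.018659,0.14238,0.012355,0.1734
100,0.018055,0.14207,0.012127,0.17225
101,0.017477,0.14175,0.011906,0.17113
102,0.016922,0.14144,0.01169,0.17005
103,0.016389,0.14113,0.01148,0.169
104,0.015879,0.14082,0.011276,0.16797
105,0.015388,0.14051,0.011077,0.16698
106,0.014917,0.1402,0.010883,0.16601
107,0.014465,0.1399,0.010694,0.16506
108,0.01403,0.1396,0.01051,0.16414
109,0.013612,0.1393,0.010331,0.16324
110,0.01321,0.139,0.010156,0.16236
111,0.012823,0.1387,0.0099862,0.16151
112,0.012451,0.1384,0.0098201,0.16068
113,0.012092,0.13811,0.0096582,0.15986
114,0.011747,0.13782,0.0095002,0.15906
115,0.011415,0.13753,0.0093461,0.15829
116,0.011094,0.13724,0.0091956,0.15753
117,0.010785,0.13695,0.0090488,0.15678
118,0.010487,0.13666,0.0089054,0.15606
119,0.0102,0.13638,0.0087654,0.15534
120,0.0099227,0.1361,0.0086287,0.15465
121,0.0096551,0.13581,0.0084951,0.15396
122,0.0093968,0.13553,0.0083646,0.1533
123,0.0091474,0.13526,0.0082371,0.15264
124,0.0089064,0.13498,0.0081125,0.152
125,0.0086736,0.1347,0.0079906,0.15137
126,0.0084486,0.13443,0.0078715,0.15075
127,0.0082311,0.13416,0.007755,0.15014
128,0.0080208,0.13389,0.0076411,0.14955
129,0.0078174,0.13362,0.0075296,0.14896
130,0.0076206,0.13335,0.0074206,0.14839
131,0.0074301,0.13308,0.0073139,0.14783
132,0.0072458,0.13282,0.0072095,0.14727
133,0.0070673,0.13256,0.0071073,0.14673
134,0.0068945,0.13229,0.0070073,0.1462
135,0.0067271,0.13203,0.0069093,0.14567
136,0.0065649,0.13177,0.0068134,0.14515
137,0.0064077,0.13152,0.0067194,0.14464
138,0.0062554,0.13126,0.0066274,0.14414
139,0.0061077,0.131,0.0065373,0.14365
140,0.0059645,0.13075,0.0064489,0.14316
141,0.0058255,0.1305,0.0063624,0.14269
142,0.0056908,0.13025,0.0062776,0.14222
143,0.00556,0.13,0.0061944,0.14175
144,0.0054331,0.12975,0.0061129,0.1413
145,0.0053099,0.1295,0.006033,0.14085
146,0.0051903,0.12926,0.0059546,0.1404
147,0.0050742,0.12901,0.0058777,0.13997
148,0.0049613,0.12877,0.0058023,0.13953
149,0.0048517,0.12853,0.0057284,0.13911
150,0.0047453,0.12829,0.0056558,0.13869
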