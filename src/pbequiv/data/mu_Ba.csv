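energy_keV,photoelectric,incoherent,coherent,total
1,8462.5,0.0094585,8.616,8471.1
2,2255.2,0.028434,7.5397,2262.7
3,841.68,0.046412,6.5102,848.23
4,406.73,0.06101,5.6652,412.46
5,229.23,0.072717,4.9791,234.28
5.247,202.45,0.075232,4.8305,207.35
5.247,630.59,0.075272,4.8281,635.5
5.6236,512.81,0.078868,4.6147,517.5
5.6236,711.25,0.078905,4.6125,715.94
5.9888,596.95,0.082151,4.4189,601.45
5.9888,687.91,0.082185,4.4168,692.4
6,685.25,0.082265,4.4121,689.75
7,462.55,0.090181,3.9351,466.57
8,327.13,0.09682,3.5289,330.75
9,240.14,0.10243,3.1799,243.43
10,181.56,0.10718,2.8784,184.55
11,140.73,0.11123,2.6166,143.46
12,111.34,0.11468,2.3882,113.84
13,89.642,0.11764,2.1882,91.947
14,73.293,0.12017,2.0122,75.425
15,60.73,0.12234,1.8567,62.709
16,50.909,0.1242,1.7188,52.752
17,43.116,0.12581,1.5959,44.838
18,36.85,0.12719,1.4861,38.464
19,31.753,0.12837,1.3874,33.269
20,27.561,0.12939,1.2986,28.989
21,24.082,0.13027,1.2182,25.431
22,21.169,0.13102,1.1453,22.445
23,18.711,0.13165,1.079,19.921
24,16.621,0.1322,1.0184,17.771
25,14.833,0.13265,0.96299,15.928
26,13.294,0.13304,0.91209,14.339
27,11.959,0.13335,0.86525,12.958
28,10.791,0.13361,0.82203,11.747
29,9.7721,0.13381,0.78206,10.688
30,8.8788,0.13397,0.74502,9.7578
31,8.0923,0.13409,0.71062,8.9371
32,7.3971,0.13417,0.67861,8.2099
33,6.7801,0.13421,0.64877,7.5631
34,6.2306,0.13423,0.6209,6.9857
35,5.7395,0.13421,0.59483,6.4686
36,5.2992,0.13418,0.5704,6.0038
37,4.9033,0.13412,0.54748,5.5849
37.4406,4.7422,0.13409,0.53787,5.4141
37.4406,28.444,0.13409,0.53778,29.116
38,27.378,0.13404,0.52594,28.038
39,25.595,0.13394,0.50566,26.235
40,23.955,0.13383,0.48656,24.575
41,22.45,0.1337,0.46854,23.052
42,21.07,0.13356,0.45152,21.655
43,19.801,0.1334,0.43542,20.37
44,18.633,0.13323,0.42017,19.187
45,17.556,0.13306,0.40573,18.095
46,16.561,0.13287,0.39202,17.086
47,15.641,0.13268,0.37901,16.152
48,14.787,0.13248,0.36664,15.287
49,13.995,0.13227,0.35487,14.482
50,13.258,0.13205,0.34366,13.734
51,12.573,0.13183,0.33298,13.038
52,11.934,0.1316,0.32279,12.388
53,11.338,0.13137,0.31307,11.782
54,10.781,0.13113,0.30378,11.216
55,10.26,0.13089,0.29491,10.686
56,9.7727,0.13065,0.28642,10.19
57,9.3156,0.1304,0.27829,9.7242
58,8.8866,0.13016,0.2705,9.2873
59,8.4837,0.1299,0.26304,8.8767
60,8.1049,0.12965,0.25588,8.4904
61,7.7483,0.12939,0.24902,8.1267
62,7.4124,0.12913,0.24242,7.7839
63,7.0957,0.12887,0.23609,7.4606
64,6.7967,0.12861,0.23,7.1554
65,6.5144,0.12835,0.22415,6.8669
66,6.2475,0.12809,0.21851,6.5941
67,5.995,0.12782,0.21309,6.3359
68,5.7559,0.12756,0.20787,6.0913
69,5.5294,0.12729,0.20283,5.8595
70,5.3146,0.12703,0.19798,5.6396
71,5.1108,0.12676,0.1933,5.4308
72,4.9172,0.12649,0.18878,5.2325
73,4.7333,0.12623,0.18442,5.044
74,4.5585,0.12596,0.18021,4.8646
75,4.3921,0.12569,0.17615,4.6939
76,4.2336,0.12542,0.17221,4.5312
77,4.0827,0.12516,0.16841,4.3762
78,3.9389,0.12489,0.16474,4.2285
79,3.8018,0.12463,0.16118,4.0876
80,3.671,0.12436,0.15774,3.9531
81,3.5438,0.12409,0.1544,3.8223
82,3.4226,0.12383,0.15117,3.6976
83,3.3068,0.12357,0.14805,3.5784
84,3.1963,0.1233,0.14501,3.4646
85,3.0907,0.12304,0.14207,3.3558
86,2.9898,0.12278,0.13922,3.2518
87,2.8933,0.12252,0.13645,3.1523
88,2.801,0.12226,0.13377,3.057
89,2.7126,0.122,0.13116,2.9657
90,2.6279,0.12174,0.12863,2.8783
91,2.5468,0.12148,0.12617,2.7944
92,2.469,0.12122,0.12378,2.714
93,2.3944,0.12096,0.12146,2.6368
94,2.3228,0.12071,0.1192,2.5627
95,2.2541,0.12045,0.11701,2.4915
96,2.1881,0.1202,0.11487,2.4231
97,2.1246,0.11995,0.1128,2.3574
98,2.0637,0.1197,0.11078,2.2941
99,2.0051,0.11945,0.10881,2.2333
100,1.9487,0.1192,0.10689,2.1748
101,1.8944,0.11895,0.10503,2.1184
102,1.8422,0.1187,0.10321,2.0641
103,1.7919,0.11845,0.10144,2.0118
104,1.7434,0.11821,0.099718,1.9613
105,1.6967,0.11796,0.098036,1.9127
106,1.6516,0.11772,0.096397,1.8657
107,1.6082,0.11748,0.094798,1.8205
108,1.5663,0.11723,0.093239,1.7768
109,1.5258,0.11699,0.091718,1.7346
110,1.4868,0.11676,0.090234,1.6938
111,1.4491,0.11652,0.088786,1.6544
112,1.4127,0.11628,0.087372,1.6163
113,1.3775,0.11604,0.085992,1.5795
114,1.3434,0.11581,0.084644,1.5439
115,1.3106,0.11558,0.083327,1.5095
116,1.2787,0.11534,0.082041,1.4761
117,1.248,0.11511,0.080785,1.4439
118,1.2182,0.11488,0.079557,1.4126
119,1.1893,0.11465,0.078356,1.3823
120,1.1614,0.11442,0.077183,1.353
121,1.1344,0.1142,0.076036,1.3246
122,1.1082,0.11397,0.074914,1.2971
123,1.0828,0.11374,0.073817,1.2704
124,1.0582,0.11352,0.072744,1.2445
125,1.0343,0.1133,0.071694,1.2193
126,1.0112,0.11308,0.070666,1.1949
127,0.98876,0.11286,0.069661,1.1713
128,0.96699,0.11264,0.068676,1.1483
129,0.94586,0.11242,0.067712,1.126
130,0.92535,0.1122,0.066769,1.1043
131,0.90544,0.11198,0.065845,1.0833
132,0.8861,0.11177,0.06494,1.0628
133,0.86732,0.11155,0.064053,1.0429
134,0.84907,0.11134,0.063185,1.0236
135,0.83134,0.11113,0.062334,1.0048
136,0.8141,0.11092,0.0615,0.98651
137,0.79734,0.11071,0.060683,0.96873
138,0.78105,0.1105,0.059882,0.95143
139,0.7652,0.11029,0.059096,0.93458
140,0.74978,0.11008,0.058326,0.91819
141,0.73478,0.10988,0.057571,0.90223
142,0.72019,0.10967,0.05683,0.88669
143,0.70598,0.10947,0.056104,0.87155
144,0.69215,0.10926,0.055391,0.85681
145,0.67868,0.10906,0.054692,0.84244
146,0.66557,0.10886,0.054006,0.82843
147,0.65279,0.10866,0.053333,0.81479
148,0.64035,0.10846,0.052672,0.80148
149,0.62822,0.10826,0.052023,0.78851
150,0.6164,0.10806,0.051386,0.77585
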