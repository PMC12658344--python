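energy_keV,photoelectric,incoherent,coherent,total
1,2301.2,0.023319,2.8239,2304
2,362.68,0.057824,2.2645,365
2.472,203.82,0.071012,2.0489,205.94
2.472,2177.8,0.071116,2.0472,2180
3,1338.5,0.083604,1.8419,1340.4
4,629.24,0.10241,1.5296,630.87
5,344.52,0.11667,1.2893,345.93
6,207.98,0.12775,1.0996,209.21
7,134.93,0.13646,0.94752,136.02
8,92.351,0.14338,0.82426,93.318
9,65.866,0.1489,0.72337,66.738
10,48.531,0.15334,0.63997,49.324
11,36.737,0.15692,0.57037,37.464
12,28.428,0.15983,0.51174,29.099
13,22.433,0.16221,0.46191,23.057
14,18.002,0.16415,0.41921,18.585
15,14.656,0.16574,0.38234,15.204
16,12.085,0.16703,0.35027,12.602
17,10.076,0.16809,0.32218,10.566
18,8.4848,0.16895,0.29744,8.9512
19,7.2085,0.16963,0.27552,7.6537
20,6.1732,0.17018,0.25601,6.5994
21,5.3249,0.17061,0.23854,5.7341
22,4.6234,0.17093,0.22285,5.0172
23,4.0384,0.17117,0.20869,4.4183
24,3.5469,0.17133,0.19587,3.914
25,3.1309,0.17142,0.18421,3.4865
26,2.7767,0.17146,0.17359,3.1217
27,2.4727,0.17144,0.16387,2.808
28,2.2101,0.17138,0.15496,2.5364
29,1.9829,0.17129,0.14676,2.3009
30,1.7854,0.17115,0.13921,2.0958
31,1.6129,0.17099,0.13223,1.9162
32,1.4617,0.17081,0.12577,1.7583
33,1.3286,0.17059,0.11977,1.6189
34,1.2109,0.17036,0.1142,1.4954
35,1.1065,0.17011,0.10901,1.3856
36,1.0136,0.16984,0.10416,1.2876
37,0.93068,0.16956,0.099639,1.1999
38,0.85643,0.16927,0.095403,1.1211
39,0.78975,0.16896,0.091434,1.0501
40,0.72971,0.16865,0.087708,0.98606
41,0.67551,0.16832,0.084206,0.92803
42,0.62646,0.16799,0.08091,0.87536
43,0.58197,0.16765,0.077804,0.82743
44,0.54154,0.1673,0.074875,0.78371
45,0.5047,0.16695,0.072108,0.74375
46,0.47107,0.16659,0.069492,0.70715
47,0.44032,0.16623,0.067016,0.67356
48,0.41214,0.16586,0.06467,0.64267
49,0.38627,0.16549,0.062445,0.61421
50,0.36249,0.16512,0.060333,0.58794
51,0.34058,0.16475,0.058327,0.56366
52,0.32038,0.16437,0.056419,0.54117
53,0.30171,0.164,0.054604,0.52031
54,0.28444,0.16362,0.052874,0.50093
55,0.26844,0.16324,0.051226,0.48291
56,0.2536,0.16286,0.049653,0.46611
57,0.23981,0.16247,0.048152,0.45044
58,0.22698,0.16209,0.046718,0.4358
59,0.21504,0.16171,0.045347,0.4221
60,0.2039,0.16133,0.044036,0.40927
61,0.19351,0.16095,0.04278,0.39724
62,0.18379,0.16057,0.041578,0.38594
63,0.17471,0.16019,0.040425,0.37532
64,0.1662,0.15981,0.03932,0.36533
65,0.15822,0.15943,0.038259,0.35591
66,0.15074,0.15905,0.037241,0.34703
67,0.14371,0.15867,0.036263,0.33864
68,0.1371,0.15829,0.035323,0.33072
69,0.13089,0.15792,0.034419,0.32323
70,0.12503,0.15754,0.033549,0.31613
71,0.11952,0.15717,0.032711,0.3094
72,0.11432,0.1568,0.031905,0.30302
73,0.1094,0.15643,0.031128,0.29696
74,0.10476,0.15606,0.030379,0.2912
75,0.10038,0.15569,0.029657,0.28573
76,0.096227,0.15533,0.02896,0.28051
77,0.092297,0.15496,0.028288,0.27555
78,0.088575,0.1546,0.027638,0.27081
79,0.085045,0.15424,0.027011,0.26629
80,0.081697,0.15388,0.026404,0.26198
81,0.078518,0.15352,0.025818,0.25785
82,0.075499,0.15316,0.025252,0.25391
83,0.072629,0.1528,0.024703,0.25014
84,0.0699,0.15245,0.024172,0.24652
85,0.067303,0.1521,0.023659,0.24306
86,0.06483,0.15175,0.023161,0.23974
87,0.062474,0.1514,0.022679,0.23655
88,0.060229,0.15105,0.022212,0.23349
89,0.058087,0.15071,0.021759,0.23056
90,0.056044,0.15037,0.021319,0.22773
91,0.054093,0.15002,0.020893,0.22501
92,0.05223,0.14969,0.02048,0.22239
93,0.050449,0.14935,0.020078,0.21987
94,0.048747,0.14901,0.019688,0.21745
95,0.047118,0.14868,0.01931,0.21511
96,0.04556,0.14834,0.018942,0.21285
97,0.044068,0.14801,0.018585,0.21067
98,0.042639,0.14768,0.018237,0.20856
99,0.04127,0.14736,0.0179,0.20653
100,0.039957,0.14703,0.017571,0.20456
101,0.038699,0.14671,0.017252,0.20266
102,0.037491,0.14639,0.016941,0.20082
103,0.036332,0.14607,0.016638,0.19904
104,0.035219,0.14575,0.016344,0.19731
105,0.03415,0.14543,0.016057,0.19564
106,0.033123,0.14512,0.015778,0.19402
107,0.032135,0.1448,0.015505,0.19244
108,0.031186,0.14449,0.01524,0.19092
109,0.030273,0.14418,0.014982,0.18943
110,0.029394,0.14387,0.01473,0.188
111,0.028548,0.14357,0.014484,0.1866
112,0.027734,0.14326,0.014245,0.18524
113,0.026949,0.14296,0.014011,0.18392
114,0.026193,0.14266,0.013783,0.18263
115,0.025464,0.14236,0.01356,0.18138
116,0.024762,0.14206,0.013343,0.18016
117,0.024084,0.14176,0.013131,0.17898
118,0.023431,0.14147,0.012924,0.17782
119,0.0228,0.14117,0.012722,0.17669
120,0.022191,0.14088,0.012525,0.1756
121,0.021603,0.14059,0.012332,0.17453
122,0.021035,0.1403,0.012143,0.17348
123,0.020487,0.14001,0.011959,0.17246
124,0.019957,0.13973,0.011779,0.17146
125,0.019444,0.13945,0.011603,0.17049
126,0.018949,0.13916,0.01143,0.16954
127,0.01847,0.13888,0.011262,0.16861
128,0.018006,0.1386,0.011097,0.16771
129,0.017557,0.13833,0.010936,0.16682
130,0.017123,0.13805,0.010779,0.16595
131,0.016703,0.13777,0.010624,0.1651
132,0.016296,0.1375,0.010473,0.16427
133,0.015901,0.13723,0.010326,0.16346
134,0.01552,0.13696,0.010181,0.16266
135,0.015149,0.13669,0.010039,0.16188
136,0.014791,0.13642,0.0099005,0.16111
137,0.014443,0.13616,0.0097646,0.16036
138,0.014106,0.13589,0.0096314,0.15963
139,0.013778,0.13563,0.009501,0.15891
140,0.013461,0.13537,0.0093732,0.1582
141,0.013153,0.13511,0.0092479,0.15751
142,0.012854,0.13485,0.0091251,0.15683
143,0.012564,0.13459,0.0090048,0.15616
144,0.012283,0.13433,0.0088867,0.1555
145,0.012009,0.13408,0.008771,0.15486
146,0.011744,0.13383,0.0086576,0.15423
147,0.011486,0.13357,0.0085463,0.1536
148,0.011235,0.13332,0.0084371,0.15299
149,0.010991,0.13307,0.00833,0.15239
150,0.010754,0.13282,0.008225,0.1518
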