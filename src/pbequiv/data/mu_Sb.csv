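energy_keV,photoelectric,incoherent,coherent,total
1,8308.3,0.010266,8.0315,8316.3
2,1699.3,0.030473,6.9876,1706.3
3,624.97,0.049268,6.0074,631.02
4,299.12,0.064375,5.2107,304.39
4.1322,275.35,0.066099,5.1192,280.54
4.1322,924.25,0.066151,5.1164,929.43
4.3804,771.33,0.069248,4.9516,776.35
4.3804,1073,0.069298,4.9489,1078.1
4.6983,884.52,0.07304,4.749,889.34
4.6983,1018,0.073086,4.7465,1022.8
5,870.94,0.076431,4.5671,875.58
6,546.57,0.086234,4.0366,550.69
7,365.72,0.094337,3.5916,369.4
8,257.09,0.10111,3.2137,260.4
9,187.75,0.10681,2.8901,190.75
10,141.25,0.11163,2.6113,143.98
11,109.05,0.11572,2.37,111.54
12,86.027,0.11919,2.16,88.306
13,69.114,0.12215,1.9766,71.212
14,56.397,0.12468,1.8156,58.337
15,46.642,0.12684,1.6736,48.442
16,39.028,0.12869,1.5479,40.705
17,32.998,0.13028,1.4362,34.565
18,28.158,0.13164,1.3363,29.626
19,24.224,0.13281,1.2468,25.603
20,20.993,0.13381,1.1663,22.293
21,18.315,0.13466,1.0935,19.543
22,16.077,0.13539,1.0276,17.24
23,14.193,0.136,0.96758,15.297
24,12.595,0.13653,0.91286,13.644
25,11.23,0.13696,0.8628,12.23
26,10.057,0.13732,0.81687,11.011
27,9.0387,0.13762,0.77462,9.951
28,8.1465,0.13785,0.73566,9.02
29,7.3692,0.13804,0.69965,8.2069
30,6.6888,0.13818,0.66629,7.4932
30.4912,6.3866,0.13823,0.65086,7.1757
30.4912,40.25,0.13823,0.65074,41.039
31,38.51,0.13827,0.63533,39.283
32,35.373,0.13833,0.60652,36.118
33,32.632,0.13836,0.57968,33.35
34,30.169,0.13835,0.55462,30.862
35,27.949,0.13832,0.53119,28.619
36,25.944,0.13827,0.50924,26.591
37,24.127,0.13819,0.48864,24.754
38,22.477,0.1381,0.4693,23.084
39,20.974,0.13798,0.4511,21.564
40,19.602,0.13785,0.43396,20.174
41,18.346,0.13771,0.41778,18.902
42,17.196,0.13755,0.40251,17.736
43,16.14,0.13738,0.38808,16.665
44,15.169,0.13719,0.37441,15.681
45,14.275,0.137,0.36146,14.774
46,13.45,0.1368,0.34918,13.936
47,12.688,0.13659,0.33752,13.162
48,11.983,0.13637,0.32644,12.445
49,11.329,0.13615,0.3159,11.781
50,10.721,0.13592,0.30587,11.163
51,10.157,0.13569,0.29631,10.589
52,9.6316,0.13544,0.2872,10.054
53,9.1418,0.1352,0.2785,9.5555
54,8.6848,0.13495,0.27019,9.0899
55,8.2577,0.1347,0.26225,8.6546
56,7.8581,0.13444,0.25466,8.2472
57,7.484,0.13418,0.2474,7.8655
58,7.1332,0.13392,0.24044,7.5075
59,6.8039,0.13365,0.23377,7.1714
60,6.4946,0.13339,0.22738,6.8554
61,6.2038,0.13312,0.22125,6.5581
62,5.9291,0.13285,0.21536,6.2773
63,5.6705,0.13258,0.2097,6.0127
64,5.4267,0.1323,0.20427,5.7633
65,5.1968,0.13203,0.19904,5.5278
66,4.9797,0.13175,0.19401,5.3054
67,4.7746,0.13148,0.18918,5.0952
68,4.5806,0.1312,0.18452,4.8963
69,4.397,0.13092,0.18003,4.7079
70,4.2231,0.13065,0.1757,4.5295
71,4.0583,0.13037,0.17153,4.3602
72,3.902,0.13009,0.1675,4.1996
73,3.7536,0.12981,0.16361,4.047
74,3.6126,0.12954,0.15986,3.902
75,3.4787,0.12926,0.15624,3.7642
76,3.3512,0.12898,0.15274,3.633
77,3.23,0.1287,0.14935,3.508
78,3.1145,0.12843,0.14608,3.389
79,3.0045,0.12815,0.14291,3.2755
80,2.8995,0.12788,0.13984,3.1673
81,2.7982,0.1276,0.13687,3.0627
82,2.7016,0.12733,0.134,2.963
83,2.6095,0.12705,0.13121,2.8677
84,2.5215,0.12678,0.12852,2.7768
85,2.4375,0.12651,0.1259,2.6899
86,2.3572,0.12624,0.12336,2.6067
87,2.2804,0.12596,0.1209,2.5272
88,2.2069,0.12569,0.11851,2.4511
89,2.1366,0.12543,0.11619,2.3783
90,2.0693,0.12516,0.11394,2.3084
91,2.0048,0.12489,0.11176,2.2415
92,1.943,0.12462,0.10963,2.1773
93,1.8838,0.12436,0.10757,2.1157
94,1.8269,0.12409,0.10556,2.0566
95,1.7723,0.12383,0.10361,1.9998
96,1.7199,0.12357,0.10171,1.9452
97,1.6696,0.12331,0.099867,1.8928
98,1.6212,0.12305,0.098071,1.8424
99,1.5747,0.12279,0.096323,1.7938
100,1.53,0.12253,0.094622,1.7472
101,1.487,0.12227,0.092965,1.7022
102,1.4456,0.12202,0.091351,1.6589
103,1.4057,0.12176,0.089779,1.6172
104,1.3673,0.12151,0.088247,1.577
105,1.3303,0.12125,0.086754,1.5383
106,1.2946,0.121,0.085298,1.5009
107,1.2602,0.12075,0.083879,1.4648
108,1.227,0.1205,0.082495,1.43
109,1.195,0.12026,0.081144,1.3964
110,1.1641,0.12001,0.079827,1.364
111,1.1343,0.11976,0.078541,1.3326
112,1.1055,0.11952,0.077286,1.3023
113,1.0776,0.11927,0.076061,1.273
114,1.0508,0.11903,0.074865,1.2446
115,1.0247,0.11879,0.073697,1.2172
116,0.9996,0.11855,0.072556,1.1907
117,0.97528,0.11831,0.071441,1.165
118,0.95175,0.11807,0.070352,1.1402
119,0.92898,0.11784,0.069287,1.1161
120,0.90694,0.1176,0.068246,1.0928
121,0.88559,0.11737,0.067229,1.0702
122,0.86492,0.11713,0.066234,1.0483
123,0.84488,0.1169,0.065261,1.027
124,0.82547,0.11667,0.064309,1.0065
125,0.80666,0.11644,0.063378,0.98648
126,0.78841,0.11621,0.062467,0.96709
127,0.77072,0.11598,0.061575,0.94828
128,0.75356,0.11576,0.060703,0.93002
129,0.73691,0.11553,0.059848,0.91229
130,0.72075,0.11531,0.059012,0.89507
131,0.70506,0.11509,0.058193,0.87834
132,0.68983,0.11486,0.057391,0.86209
133,0.67504,0.11464,0.056605,0.84629
134,0.66067,0.11442,0.055835,0.83093
135,0.64672,0.1142,0.055081,0.816
136,0.63315,0.11399,0.054342,0.80148
137,0.61997,0.11377,0.053618,0.78735
138,0.60715,0.11355,0.052908,0.77361
139,0.59469,0.11334,0.052212,0.76024
140,0.58256,0.11313,0.05153,0.74722
141,0.57077,0.11291,0.050861,0.73455
142,0.5593,0.1127,0.050205,0.72221
143,0.54814,0.11249,0.049561,0.71019
144,0.53727,0.11228,0.04893,0.69848
145,0.52669,0.11207,0.048311,0.68708
146,0.51639,0.11187,0.047703,0.67596
147,0.50636,0.11166,0.047107,0.66513
148,0.49659,0.11145,0.046522,0.65457
149,0.48707,0.11125,0.045947,0.64427
150,0.4778,0.11105,0.045383,0.63423
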