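energy_keV,photoelectric,incoherent,coherent,total
1,2171.6,0.0087202,9.8741,2181.5
1.1852,1579.4,0.011709,9.6811,1589.1
1.1852,44864,0.011777,9.6767,44874
2,3277.7,0.026675,8.7101,3286.4
3,1256.1,0.044139,7.5674,1263.8
4,614.66,0.058535,6.6153,621.33
5,349.32,0.070167,5.8367,355.23
6,218.73,0.079696,5.1905,224
7,146.65,0.087628,4.6449,151.38
7.2428,134.26,0.089341,4.526,138.88
7.2428,391.69,0.089368,4.5241,396.3
7.9302,300.57,0.093864,4.2096,304.88
7.9302,414.59,0.093889,4.2079,418.89
8,405.09,0.094308,4.1784,409.37
8.3765,357.96,0.096538,4.0209,362.07
8.3765,413.19,0.096561,4.0193,417.31
9,344.71,0.099975,3.7761,348.59
10,262.42,0.10481,3.4269,265.95
11,204.63,0.10894,3.1224,207.86
12,162.82,0.11248,2.8558,165.79
13,131.8,0.11553,2.6214,134.53
14,108.27,0.11815,2.4145,110.8
15,90.069,0.12041,2.2312,92.42
16,75.761,0.12236,2.0681,77.951
17,64.347,0.12404,1.9225,66.393
18,55.135,0.1255,1.7921,57.052
19,47.621,0.12675,1.6747,49.423
20,41.429,0.12784,1.5689,43.125
21,36.276,0.12878,1.473,37.878
22,31.953,0.12958,1.3859,33.469
23,28.298,0.13028,1.3065,29.735
24,25.185,0.13087,1.234,26.55
25,22.516,0.13138,1.1675,23.815
26,20.215,0.1318,1.1065,21.454
27,18.219,0.13216,1.0502,19.401
28,16.477,0.13246,0.99827,17.607
29,14.952,0.1327,0.9502,16.035
30,13.613,0.13289,0.90563,14.651
31,12.43,0.13304,0.86421,13.427
32,11.381,0.13315,0.82564,12.34
33,10.447,0.13322,0.78967,11.37
34,9.6139,0.13326,0.75606,10.503
35,8.867,0.13328,0.7246,9.7249
36,8.1959,0.13327,0.69511,9.0242
37,7.5897,0.13323,0.66743,8.3904
38,7.0419,0.13317,0.6414,7.8165
39,6.5462,0.13309,0.61689,7.2962
40,6.0965,0.133,0.59379,6.8233
41,5.6876,0.13289,0.57199,6.3925
42,5.3148,0.13277,0.55138,5.999
43,4.9743,0.13263,0.53189,5.6388
44,4.6626,0.13248,0.51343,5.3085
45,4.3767,0.13232,0.49592,5.0049
46,4.114,0.13214,0.47931,4.7254
47,3.8721,0.13196,0.46353,4.4675
48,3.649,0.13178,0.44852,4.2293
49,3.4429,0.13158,0.43424,4.0087
50,3.2521,0.13138,0.42064,3.8042
50.2391,3.209,0.13133,0.41751,3.7579
50.2391,17.968,0.13133,0.41746,18.517
51,17.295,0.13117,0.40768,17.833
52,16.457,0.13095,0.3953,16.983
53,15.667,0.13073,0.38349,16.181
54,14.918,0.13051,0.37221,15.421
55,14.217,0.13028,0.36141,14.708
56,13.559,0.13004,0.35109,14.04
57,12.942,0.12981,0.3412,13.413
58,12.362,0.12957,0.33173,12.824
59,11.817,0.12932,0.32265,12.269
60,11.304,0.12908,0.31394,11.747
61,10.82,0.12883,0.30557,11.254
62,10.364,0.12858,0.29754,10.79
63,9.9331,0.12833,0.28983,10.351
64,9.5261,0.12807,0.28241,9.9366
65,9.1413,0.12782,0.27527,9.5444
66,8.7772,0.12756,0.2684,9.1732
67,8.4324,0.1273,0.26178,8.8215
68,8.1056,0.12705,0.25541,8.488
69,7.7955,0.12679,0.24927,8.1715
70,7.5011,0.12653,0.24335,7.871
71,7.2215,0.12627,0.23763,7.5854
72,6.9557,0.126,0.23212,7.3138
73,6.7028,0.12574,0.22679,7.0554
74,6.4622,0.12548,0.22165,6.8093
75,6.2329,0.12522,0.21668,6.5748
76,6.0145,0.12496,0.21188,6.3513
77,5.8061,0.1247,0.20723,6.138
78,5.6073,0.12444,0.20274,5.9345
79,5.4176,0.12417,0.19839,5.7401
80,5.2363,0.12391,0.19417,5.5544
81,5.0624,0.12365,0.1901,5.3761
82,4.8962,0.12339,0.18615,5.2057
83,4.7372,0.12313,0.18232,5.0427
84,4.5852,0.12287,0.1786,4.8867
85,4.4397,0.12261,0.175,4.7373
86,4.3003,0.12236,0.17151,4.5942
87,4.1668,0.1221,0.16812,4.457
88,4.0388,0.12184,0.16483,4.3254
89,3.916,0.12159,0.16164,4.1992
90,3.7982,0.12133,0.15854,4.0781
91,3.6852,0.12108,0.15553,3.9618
92,3.5766,0.12082,0.1526,3.85
93,3.4723,0.12057,0.14975,3.7427
94,3.3721,0.12032,0.14698,3.6394
95,3.2757,0.12006,0.14429,3.5401
96,3.183,0.11981,0.14167,3.4445
97,3.0938,0.11956,0.13913,3.3525
98,3.0079,0.11932,0.13665,3.2639
99,2.9252,0.11907,0.13423,3.1785
100,2.8456,0.11882,0.13188,3.0963
101,2.7679,0.11857,0.12959,3.016
102,2.6921,0.11833,0.12736,2.9378
103,2.6192,0.11809,0.12519,2.8625
104,2.5489,0.11784,0.12307,2.7898
105,2.4812,0.1176,0.12101,2.7198
106,2.4158,0.11736,0.119,2.6522
107,2.3528,0.11712,0.11703,2.587
108,2.2921,0.11688,0.11512,2.5241
109,2.2334,0.11664,0.11325,2.4633
110,2.1768,0.11641,0.11143,2.4046
111,2.122,0.11617,0.10965,2.3479
112,2.0692,0.11594,0.10791,2.293
113,2.0181,0.1157,0.10621,2.24
114,1.9687,0.11547,0.10455,2.1888
115,1.921,0.11524,0.10294,2.1392
116,1.8748,0.11501,0.10135,2.0912
117,1.8301,0.11478,0.099809,2.0447
118,1.7869,0.11455,0.098299,1.9997
119,1.745,0.11432,0.096823,1.9561
120,1.7044,0.1141,0.09538,1.9139
121,1.6652,0.11387,0.093969,1.873
122,1.6271,0.11365,0.092589,1.8333
123,1.5902,0.11342,0.091239,1.7949
124,1.5545,0.1132,0.089918,1.7576
125,1.5198,0.11298,0.088626,1.7214
126,1.4862,0.11276,0.087361,1.6863
127,1.4536,0.11254,0.086123,1.6522
128,1.4219,0.11232,0.084912,1.6191
129,1.3912,0.11211,0.083725,1.587
130,1.3614,0.11189,0.082564,1.5558
131,1.3324,0.11167,0.081426,1.5255
132,1.3043,0.11146,0.080312,1.496
133,1.2769,0.11125,0.07922,1.4674
134,1.2504,0.11104,0.07815,1.4396
135,1.2246,0.11083,0.077102,1.4125
136,1.1995,0.11062,0.076075,1.3862
137,1.1751,0.11041,0.075068,1.3606
138,1.1514,0.1102,0.074081,1.3357
139,1.1283,0.10999,0.073113,1.3114
140,1.1059,0.10979,0.072164,1.2878
141,1.084,0.10958,0.071234,1.2648
142,1.0627,0.10938,0.070321,1.2424
143,1.042,0.10918,0.069426,1.2206
144,1.0219,0.10897,0.068547,1.1994
145,1.0023,0.10877,0.067686,1.1787
146,0.98314,0.10857,0.06684,1.1586
147,0.96452,0.10837,0.06601,1.1389
148,0.94637,0.10818,0.065195,1.1197
149,0.92869,0.10798,0.064395,1.1011
150,0.91145,0.10778,0.06361,1.0828
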