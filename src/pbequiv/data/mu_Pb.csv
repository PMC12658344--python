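energy_keV,photoelectric,incoherent,coherent,total
1,5006.1,0.0073046,12.399,5018.5
2,1229.2,0.023036,11.092,1240.3
2.484,765.66,0.031008,10.425,776.12
2.484,10055,0.031072,10.42,10065
3,1933.1,0.039088,9.7466,1942.9
4,1225.6,0.052719,8.5921,1234.2
5,711.59,0.063903,7.6339,719.28
6,451.78,0.073146,6.832,458.68
7,306.16,0.080893,6.1505,312.39
8,217.83,0.087463,5.5641,223.49
9,160.97,0.093083,5.0547,166.12
10,122.5,0.097914,4.6093,127.21
11,95.614,0.10208,4.2181,99.935
12,76.193,0.10569,3.873,80.171
13,61.798,0.10881,3.5675,65.475
13.0352,61.387,0.10891,3.558,65.054
13.0352,157.75,0.10892,3.5569,161.42
14,130.18,0.11153,3.2962,133.59
15,107.83,0.11388,3.0545,111
15.2,104.03,0.11431,3.0098,107.15
15.2,145.85,0.11432,3.0089,148.97
15.8608,130.11,0.11566,2.8675,133.1
15.8608,150.39,0.11567,2.8667,153.37
16,147.14,0.11593,2.8384,150.09
17,126.09,0.11772,2.6446,128.85
18,108.87,0.11928,2.4702,111.46
19,94.698,0.12063,2.3128,97.132
20,82.923,0.12181,2.1703,85.215
21,73.051,0.12284,2.0408,75.215
22,64.711,0.12374,1.9229,66.758
23,57.613,0.12452,1.8152,59.553
24,51.532,0.12519,1.7166,53.373
25,46.288,0.12577,1.6261,48.04
26,41.743,0.12627,1.5427,43.412
27,37.775,0.1267,1.4658,39.368
28,34.292,0.12706,1.3947,35.813
29,31.231,0.12737,1.3288,32.687
30,28.531,0.12762,1.2676,29.926
31,26.134,0.12783,1.2107,27.473
32,24,0.12799,1.1576,25.286
33,22.093,0.12812,1.1081,23.329
34,20.387,0.12821,1.0617,21.577
35,18.855,0.12828,1.0183,20.001
36,17.475,0.12831,0.97755,18.581
37,16.229,0.12832,0.93927,17.297
38,15.101,0.1283,0.90325,16.132
39,14.077,0.12827,0.86931,15.074
40,13.145,0.12822,0.83729,14.11
41,12.294,0.12814,0.80704,13.23
42,11.517,0.12806,0.77844,12.424
43,10.805,0.12795,0.75136,11.684
44,10.151,0.12784,0.7257,11.005
45,9.5504,0.12771,0.70135,10.379
46,8.9966,0.12757,0.67823,9.8024
47,8.4855,0.12743,0.65625,9.2691
48,8.0129,0.12727,0.63533,8.7755
49,7.5754,0.1271,0.61542,8.3179
50,7.1696,0.12693,0.59644,7.8929
51,6.7927,0.12675,0.57833,7.4977
52,6.4421,0.12656,0.56105,7.1297
53,6.1156,0.12636,0.54454,6.7865
54,5.8111,0.12617,0.52875,6.4661
55,5.5268,0.12596,0.51365,6.1664
56,5.261,0.12575,0.49919,5.886
57,5.012,0.12554,0.48534,5.6229
58,4.7786,0.12532,0.47206,5.376
59,4.5597,0.1251,0.45932,5.1442
60,4.3542,0.12488,0.4471,4.9262
61,4.161,0.12465,0.43536,4.721
62,3.9793,0.12443,0.42408,4.5278
63,3.8081,0.12419,0.41323,4.3455
64,3.6467,0.12396,0.4028,4.1735
65,3.4945,0.12373,0.39276,4.011
66,3.3507,0.12349,0.38309,3.8573
67,3.2148,0.12325,0.37378,3.7118
68,3.0862,0.12301,0.3648,3.574
69,2.9645,0.12277,0.35615,3.4434
70,2.8491,0.12253,0.3478,3.3194
71,2.7397,0.12229,0.33974,3.2017
72,2.6359,0.12204,0.33196,3.0899
73,2.5374,0.1218,0.32444,2.9836
74,2.4438,0.12155,0.31718,2.8826
75,2.3549,0.12131,0.31016,2.7864
76,2.2703,0.12106,0.30336,2.6947
77,2.1898,0.12082,0.2968,2.6074
78,2.1131,0.12057,0.29044,2.5241
79,2.04,0.12033,0.28428,2.4446
80,1.9703,0.12008,0.27832,2.3687
81,1.9038,0.11984,0.27254,2.2962
82,1.8404,0.11959,0.26695,2.2269
83,1.7797,0.11935,0.26152,2.1606
84,1.7218,0.1191,0.25626,2.0971
85,1.6663,0.11886,0.25115,2.0363
86,1.6133,0.11861,0.2462,1.9781
87,1.5625,0.11837,0.24139,1.9223
88,1.5139,0.11812,0.23672,1.8688
88.005,1.5138,0.11812,0.23671,1.8686
88.005,7.2281,0.11812,0.23669,7.5829
89,7.0245,0.11788,0.23219,7.3746
90,6.8272,0.11764,0.22778,7.1726
91,6.6373,0.1174,0.2235,6.9782
92,6.4545,0.11716,0.21934,6.791
93,6.2784,0.11692,0.21529,6.6106
94,6.1087,0.11668,0.21136,6.4368
95,5.9452,0.11644,0.20753,6.2692
96,5.7875,0.1162,0.2038,6.1075
97,5.6354,0.11596,0.20018,5.9515
98,5.4886,0.11572,0.19665,5.801
99,5.3469,0.11549,0.19321,5.6556
100,5.2102,0.11525,0.18986,5.5153
101,5.0776,0.11502,0.1866,5.3792
102,4.9493,0.11478,0.18342,5.2476
103,4.8255,0.11455,0.18032,5.1204
104,4.7058,0.11432,0.1773,4.9974
105,4.5901,0.11409,0.17436,4.8786
106,4.4783,0.11386,0.17148,4.7636
107,4.3701,0.11363,0.16868,4.6524
108,4.2655,0.1134,0.16595,4.5449
109,4.1643,0.11317,0.16328,4.4407
110,4.0663,0.11295,0.16068,4.3399
111,3.9714,0.11272,0.15814,4.2422
112,3.8795,0.1125,0.15565,4.1476
113,3.7904,0.11227,0.15323,4.0559
114,3.7041,0.11205,0.15086,3.9671
115,3.6205,0.11183,0.14855,3.8809
116,3.5394,0.11161,0.14629,3.7973
117,3.4608,0.11139,0.14408,3.7163
118,3.3845,0.11117,0.14192,3.6376
119,3.3105,0.11095,0.1398,3.5613
120,3.2387,0.11073,0.13774,3.4872
121,3.169,0.11052,0.13572,3.4152
122,3.1013,0.1103,0.13374,3.3453
123,3.0355,0.11009,0.13181,3.2774
124,2.9717,0.10987,0.12992,3.2115
125,2.9093,0.10966,0.12807,3.147
126,2.8485,0.10945,0.12626,3.0842
127,2.7893,0.10924,0.12448,3.0231
128,2.7319,0.10903,0.12275,2.9637
129,2.6761,0.10882,0.12104,2.9059
130,2.6218,0.10861,0.11938,2.8498
131,2.569,0.10841,0.11775,2.7952
132,2.5177,0.1082,0.11615,2.742
133,2.4678,0.108,0.11458,2.6903
134,2.4192,0.10779,0.11305,2.64
135,2.3719,0.10759,0.11155,2.591
136,2.3259,0.10739,0.11007,2.5433
137,2.2811,0.10719,0.10863,2.4969
138,2.2375,0.10699,0.10721,2.4517
139,2.195,0.10679,0.10582,2.4076
140,2.1536,0.10659,0.10446,2.3646
141,2.1133,0.10639,0.10312,2.3228
142,2.074,0.1062,0.10181,2.282
143,2.0357,0.106,0.10052,2.2422
144,1.9983,0.10581,0.099262,2.2034
145,1.9619,0.10561,0.098024,2.1656
146,1.9264,0.10542,0.096808,2.1287
147,1.8918,0.10523,0.095615,2.0927
148,1.8581,0.10504,0.094444,2.0575
149,1.8251,0.10485,0.093294,2.0233
150,1.793,0.10466,0.092165,1.9898
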