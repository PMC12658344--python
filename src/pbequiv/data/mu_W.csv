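energy_keV,photoelectric,incoherent,coherent,total
1,3514.5,0.0079052,11.345,3525.9
1.8092,1048.8,0.021222,10.348,1059.1
1.8092,19660,0.021293,10.342,19671
2,3849.3,0.024625,10.092,3859.4
3,1867.6,0.041353,8.8264,1876.5
4,931.39,0.055381,7.754,939.19
5,534.68,0.066815,6.8696,541.62
6,337.02,0.076229,6.132,343.23
7,227.2,0.084097,5.507,232.79
8,161.02,0.090752,4.9704,166.08
9,118.57,0.096425,4.5057,123.18
10,89.936,0.10129,4.1006,94.138
10.2068,85.258,0.10219,4.0241,89.384
10.2068,235.2,0.10221,4.0226,239.32
11,187.57,0.10547,3.7457,191.42
11.544,164.53,0.10748,3.5717,168.21
11.544,228.73,0.1075,3.5705,232.4
12,205.97,0.10907,3.4337,209.51
12.0998,201.48,0.10939,3.4052,204.99
12.0998,232.84,0.10941,3.4041,236.35
13,194.07,0.11218,3.1583,197.34
14,160.34,0.11487,2.9143,163.37
15,134.11,0.1172,2.6974,136.92
16,113.34,0.11922,2.5039,115.96
17,96.702,0.12098,2.3307,99.154
18,83.212,0.1225,2.1751,85.51
19,72.152,0.12382,2.0349,74.311
20,62.992,0.12497,1.9081,65.025
21,55.335,0.12597,1.7932,57.254
22,48.883,0.12683,1.6885,50.699
23,43.409,0.12758,1.5931,45.13
24,38.731,0.12822,1.5057,40.364
25,34.708,0.12878,1.4256,36.263
26,31.232,0.12925,1.3519,32.713
27,28.206,0.12965,1.284,29.619
28,25.554,0.12999,1.2212,26.906
29,23.23,0.13027,1.163,24.523
30,21.184,0.1305,1.109,22.423
31,19.374,0.13068,1.0588,20.564
32,17.768,0.13082,1.0121,18.911
33,16.337,0.13093,0.96843,17.436
34,15.058,0.131,0.92763,16.116
35,13.911,0.13104,0.88941,14.931
36,12.879,0.13106,0.85358,13.863
37,11.947,0.13105,0.81991,12.898
38,11.105,0.13102,0.78825,12.024
39,10.341,0.13096,0.75842,11.231
40,9.6468,0.13089,0.73029,10.508
41,9.0138,0.1308,0.70373,9.8483
42,8.4357,0.1307,0.67862,9.245
43,7.9066,0.13058,0.65485,8.692
44,7.4213,0.13045,0.63234,8.1841
45,6.9748,0.13031,0.61098,7.716
46,6.5636,0.13016,0.5907,7.2845
47,6.1845,0.12999,0.57143,6.886
48,5.8345,0.12982,0.5531,6.5174
49,5.5106,0.12964,0.53565,6.1759
50,5.2106,0.12946,0.51902,5.8591
51,4.9319,0.12926,0.50317,5.5643
52,4.6729,0.12906,0.48803,5.29
53,4.4315,0.12886,0.47358,5.0339
54,4.2063,0.12864,0.45976,4.7948
55,3.9964,0.12843,0.44655,4.5714
56,3.8004,0.12821,0.4339,4.3626
57,3.6173,0.12798,0.42179,4.167
58,3.4458,0.12776,0.41018,3.9837
59,3.2852,0.12753,0.39904,3.8118
60,3.1345,0.12729,0.38836,3.6502
61,2.9931,0.12706,0.3781,3.4982
62,2.8601,0.12682,0.36824,3.3552
63,2.7351,0.12658,0.35877,3.2204
64,2.6173,0.12633,0.34966,3.0933
65,2.5062,0.12609,0.34089,2.9732
66,2.4015,0.12584,0.33245,2.8598
67,2.3026,0.12559,0.32432,2.7525
68,2.2091,0.12534,0.31649,2.6509
69,2.1207,0.1251,0.30894,2.5547
69.525,2.0763,0.12496,0.3051,2.5064
69.525,10.68,0.12496,0.30507,11.11
70,10.501,0.12484,0.30165,10.928
71,10.135,0.12459,0.29462,10.554
72,9.7835,0.12434,0.28784,10.196
73,9.4456,0.12409,0.28129,9.851
74,9.1143,0.12384,0.27495,9.5131
75,8.7988,0.12358,0.26884,9.1912
76,8.4982,0.12333,0.26292,8.8844
77,8.2115,0.12308,0.25719,8.5918
78,7.9381,0.12282,0.25166,8.3126
79,7.677,0.12257,0.24629,8.0459
80,7.4276,0.12231,0.2411,7.7911
81,7.1903,0.12206,0.23607,7.5484
82,6.963,0.12181,0.2312,7.316
83,6.7454,0.12156,0.22648,7.0934
84,6.5368,0.1213,0.2219,6.88
85,6.3369,0.12105,0.21746,6.6754
86,6.1452,0.1208,0.21315,6.4791
87,5.9612,0.12055,0.20896,6.2907
88,5.7845,0.1203,0.2049,6.1097
89,5.6149,0.12005,0.20096,5.9359
90,5.4519,0.1198,0.19713,5.7688
91,5.2943,0.11955,0.1934,5.6073
92,5.1423,0.1193,0.18978,5.4514
93,4.9962,0.11906,0.18627,5.3015
94,4.8557,0.11881,0.18285,5.1573
95,4.7205,0.11856,0.17952,5.0186
96,4.5904,0.11832,0.17628,4.885
97,4.4651,0.11808,0.17313,4.7563
98,4.3444,0.11783,0.17007,4.6323
99,4.2282,0.11759,0.16708,4.5128
100,4.1161,0.11735,0.16417,4.3976
101,4.008,0.11711,0.16134,4.2865
102,3.9038,0.11687,0.15858,4.1792
103,3.8032,0.11663,0.15589,4.0757
104,3.7061,0.11639,0.15327,3.9757
105,3.6123,0.11616,0.15071,3.8792
106,3.5218,0.11592,0.14822,3.7859
107,3.4343,0.11568,0.14579,3.6958
108,3.3497,0.11545,0.14341,3.6086
109,3.268,0.11522,0.1411,3.5243
110,3.1889,0.11499,0.13884,3.4427
111,3.1124,0.11475,0.13663,3.3638
112,3.0384,0.11452,0.13448,3.2874
113,2.9668,0.1143,0.13238,3.2135
114,2.8974,0.11407,0.13032,3.1418
115,2.8302,0.11384,0.12832,3.0724
116,2.7652,0.11361,0.12636,3.0051
117,2.7021,0.11339,0.12444,2.9399
118,2.641,0.11316,0.12257,2.8767
119,2.5817,0.11294,0.12074,2.8154
120,2.5243,0.11272,0.11895,2.7559
121,2.4685,0.1125,0.11719,2.6982
122,2.4144,0.11228,0.11548,2.6422
123,2.362,0.11206,0.11381,2.5878
124,2.311,0.11184,0.11217,2.535
125,2.2616,0.11162,0.11056,2.4837
126,2.2135,0.11141,0.10899,2.4339
127,2.1669,0.11119,0.10746,2.3855
128,2.1215,0.11098,0.10595,2.3384
129,2.0775,0.11077,0.10448,2.2927
130,2.0346,0.11055,0.10304,2.2482
131,1.993,0.11034,0.10162,2.205
132,1.9525,0.11013,0.10024,2.1629
133,1.9131,0.10992,0.098884,2.1219
134,1.8748,0.10971,0.097555,2.0821
135,1.8376,0.10951,0.096253,2.0433
136,1.8013,0.1093,0.094977,2.0056
137,1.766,0.1091,0.093725,1.9688
138,1.7316,0.10889,0.092499,1.933
139,1.6981,0.10869,0.091296,1.8981
140,1.6647,0.10849,0.090116,1.8633
141,1.6322,0.10829,0.08896,1.8294
142,1.6005,0.10808,0.087825,1.7964
143,1.5697,0.10789,0.086712,1.7643
144,1.5396,0.10769,0.08562,1.7329
145,1.5104,0.10749,0.084548,1.7024
146,1.4819,0.10729,0.083496,1.6727
147,1.4541,0.1071,0.082464,1.6437
148,1.4271,0.1069,0.081451,1.6154
149,1.4007,0.10671,0.080456,1.5879
150,1.375,0.10652,0.079479,1.561
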