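energy_keV,photoelectric,incoherent,coherent,total
1,2072.5,0.037536,0.97437,2073.5
2,283.14,0.078855,0.72302,283.95
3,84.575,0.10562,0.55815,85.239
4,35.162,0.12403,0.44301,35.729
5,17.64,0.13722,0.35908,18.136
6,9.9703,0.14685,0.29645,10.414
7,6.1324,0.154,0.2488,6.5352
8,4.0163,0.15936,0.21187,4.3875
9,2.7595,0.16345,0.18273,3.1056
10,1.965,0.16659,0.15935,2.291
11,1.4446,0.16902,0.1403,1.7539
12,1.0904,0.17091,0.12457,1.3858
13,0.84142,0.17238,0.11141,1.1252
14,0.66171,0.17352,0.10028,0.93551
15,0.52893,0.1744,0.090789,0.79412
16,0.42886,0.17507,0.082611,0.68654
17,0.35209,0.17556,0.075513,0.60317
18,0.29229,0.17592,0.06931,0.53752
19,0.24506,0.17616,0.063853,0.48507
20,0.2073,0.1763,0.059026,0.44263
21,0.17677,0.17636,0.054733,0.40786
22,0.15184,0.17635,0.050897,0.37909
23,0.13129,0.17629,0.047455,0.35503
24,0.11422,0.17617,0.044353,0.33474
25,0.099924,0.17601,0.041548,0.31748
26,0.08787,0.17581,0.039003,0.30268
27,0.077607,0.17558,0.036686,0.28987
28,0.068783,0.17532,0.03457,0.27867
29,0.061223,0.17504,0.032632,0.26889
30,0.05471,0.17474,0.030854,0.2603
31,0.049072,0.17442,0.029218,0.25271
32,0.044167,0.17408,0.027708,0.24596
33,0.039883,0.17373,0.026313,0.23993
34,0.036124,0.17337,0.025021,0.23452
35,0.032814,0.173,0.023822,0.22964
36,0.029889,0.17262,0.022707,0.22521
37,0.027294,0.17223,0.021669,0.22119
38,0.024986,0.17184,0.0207,0.21752
39,0.022925,0.17144,0.019795,0.21416
40,0.021081,0.17103,0.018948,0.21106
41,0.019425,0.17062,0.018154,0.2082
42,0.017935,0.17021,0.017409,0.20555
43,0.01659,0.16979,0.016709,0.20309
44,0.015374,0.16937,0.016051,0.2008
45,0.014272,0.16896,0.01543,0.19866
46,0.01327,0.16853,0.014845,0.19665
47,0.012358,0.16811,0.014293,0.19476
48,0.011526,0.16769,0.01377,0.19299
49,0.010766,0.16727,0.013276,0.19131
50,0.010069,0.16684,0.012808,0.18972
51,0.0094307,0.16642,0.012364,0.18821
52,0.0088438,0.166,0.011943,0.18678
53,0.0083036,0.16557,0.011543,0.18542
54,0.0078057,0.16515,0.011163,0.18412
55,0.007346,0.16473,0.010801,0.18288
56,0.0069209,0.16431,0.010457,0.18169
57,0.0065274,0.16389,0.010129,0.18055
58,0.0061626,0.16347,0.0098157,0.17945
59,0.0058238,0.16306,0.0095169,0.1784
60,0.005509,0.16264,0.0092315,0.17738
61,0.005216,0.16223,0.0089588,0.1764
62,0.004943,0.16182,0.0086979,0.17546
63,0.0046883,0.16141,0.0084483,0.17454
64,0.0044505,0.161,0.0082092,0.17366
65,0.0042282,0.16059,0.0079802,0.1728
66,0.0040201,0.16019,0.0077605,0.17197
67,0.0038252,0.15978,0.0075498,0.17116
68,0.0036424,0.15938,0.0073476,0.17037
69,0.0034708,0.15898,0.0071533,0.16961
70,0.0033097,0.15859,0.0069667,0.16886
71,0.0031581,0.15819,0.0067872,0.16814
72,0.0030155,0.1578,0.0066146,0.16743
73,0.0028812,0.15741,0.0064484,0.16674
74,0.0027546,0.15702,0.0062884,0.16606
75,0.0026351,0.15663,0.0061343,0.1654
76,0.0025223,0.15625,0.0059858,0.16476
77,0.0024157,0.15587,0.0058426,0.16412
78,0.0023149,0.15549,0.0057045,0.16351
79,0.0022196,0.15511,0.0055711,0.1629
80,0.0021293,0.15473,0.0054424,0.1623
81,0.0020437,0.15436,0.0053181,0.16172
82,0.0019625,0.15399,0.005198,0.16115
83,0.0018855,0.15362,0.0050819,0.16058
84,0.0018124,0.15325,0.0049697,0.16003
85,0.001743,0.15288,0.0048611,0.15949
86,0.001677,0.15252,0.004756,0.15895
87,0.0016142,0.15216,0.0046543,0.15843
88,0.0015544,0.1518,0.0045558,0.15791
89,0.0014975,0.15144,0.0044604,0.1574
90,0.0014433,0.15109,0.0043679,0.1569
91,0.0013916,0.15073,0.0042783,0.1564
92,0.0013423,0.15038,0.0041914,0.15592
93,0.0012953,0.15004,0.0041071,0.15544
94,0.0012504,0.14969,0.0040254,0.15496
95,0.0012075,0.14934,0.003946,0.1545
96,0.0011664,0.149,0.003869,0.15404
97,0.0011272,0.14866,0.0037941,0.15358
98,0.0010897,0.14832,0.0037215,0.15313
99,0.0010538,0.14799,0.0036508,0.15269
100,0.0010195,0.14765,0.0035822,0.15225
101,0.00098655,0.14732,0.0035155,0.15182
102,0.00095501,0.14699,0.0034506,0.15139
103,0.00092476,0.14666,0.0033875,0.15097
104,0.00089576,0.14633,0.0033261,0.15056
105,0.00086793,0.14601,0.0032664,0.15014
106,0.00084122,0.14569,0.0032082,0.14974
107,0.00081557,0.14536,0.0031516,0.14933
108,0.00079093,0.14505,0.0030965,0.14893
109,0.00076725,0.14473,0.0030428,0.14854
110,0.00074449,0.14441,0.0029904,0.14815
111,0.0007226,0.1441,0.0029394,0.14776
112,0.00070155,0.14379,0.0028897,0.14738
113,0.00068129,0.14348,0.0028413,0.147
114,0.00066178,0.14317,0.002794,0.14663
115,0.000643,0.14286,0.0027479,0.14626
116,0.0006249,0.14256,0.002703,0.14589
117,0.00060747,0.14226,0.0026591,0.14552
118,0.00059066,0.14196,0.0026163,0.14516
119,0.00057446,0.14166,0.0025745,0.14481
120,0.00055883,0.14136,0.0025337,0.14445
121,0.00054375,0.14106,0.0024938,0.1441
122,0.0005292,0.14077,0.0024549,0.14376
123,0.00051515,0.14048,0.0024169,0.14341
124,0.00050159,0.14019,0.0023798,0.14307
125,0.00048849,0.1399,0.0023435,0.14273
126,0.00047583,0.13961,0.002308,0.1424
127,0.00046359,0.13933,0.0022733,0.14206
128,0.00045176,0.13904,0.0022394,0.14173
129,0.00044033,0.13876,0.0022063,0.14141
130,0.00042926,0.13848,0.0021739,0.14108
131,0.00041856,0.1382,0.0021421,0.14076
132,0.00040821,0.13792,0.0021111,0.14044
133,0.00039818,0.13765,0.0020808,0.14013
134,0.00038847,0.13737,0.002051,0.13981
135,0.00037908,0.1371,0.002022,0.1395
136,0.00036997,0.13683,0.0019935,0.13919
137,0.00036115,0.13656,0.0019656,0.13888
138,0.0003526,0.13629,0.0019383,0.13858
139,0.00034431,0.13602,0.0019116,0.13828
140,0.00033628,0.13576,0.0018854,0.13798
141,0.00032849,0.13549,0.0018597,0.13768
142,0.00032093,0.13523,0.0018346,0.13739
143,0.0003136,0.13497,0.00181,0.13709
144,0.00030648,0.13471,0.0017858,0.1368
145,0.00029958,0.13445,0.0017621,0.13651
146,0.00029287,0.13419,0.001739,0.13623
147,0.00028636,0.13394,0.0017162,0.13594
148,0.00028004,0.13369,0.0016939,0.13566
149,0.0002739,0.13343,0.001672,0.13538
150,0.00026793,0.13318,0.0016506,0.1351
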