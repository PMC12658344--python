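energy_keV,photoelectric,incoherent,coherent,total
1,2687.5,0.021708,2.895,2690.4
2,426.84,0.054379,2.3322,429.22
2.8224,166.97,0.075184,1.9703,169.01
2.8224,1719.7,0.075272,1.9688,1721.7
3,1481.8,0.079044,1.9027,1483.7
4,701.49,0.097111,1.5841,703.17
5,386.94,0.11085,1.3383,388.39
6,235.25,0.12155,1.1436,236.51
7,153.26,0.12999,0.98717,154.38
8,105.27,0.13671,0.85999,106.27
9,75.316,0.1421,0.75563,76.214
10,55.63,0.14644,0.66918,56.445
11,42.221,0.14995,0.59691,42.968
12,32.776,0.15282,0.53594,33.465
13,25.909,0.15516,0.48406,26.549
14,20.819,0.15707,0.43956,21.415
15,16.971,0.15864,0.40109,17.531
16,14.009,0.15993,0.36761,14.537
17,11.694,0.16099,0.33827,12.193
18,9.8576,0.16184,0.31241,10.332
19,8.3833,0.16254,0.28949,8.8353
20,7.1862,0.16309,0.26907,7.6184
21,6.2044,0.16353,0.2508,6.6187
22,5.3918,0.16386,0.23437,5.79
23,4.7136,0.16411,0.21954,5.0972
24,4.1432,0.16428,0.2061,4.5136
25,3.6602,0.16439,0.19389,4.0185
26,3.2485,0.16444,0.18275,3.5957
27,2.895,0.16444,0.17255,3.232
28,2.5893,0.1644,0.16321,2.9169
29,2.3246,0.16432,0.15461,2.6436
30,2.0944,0.16421,0.14668,2.4053
31,1.8933,0.16406,0.13935,2.1967
32,1.7167,0.16389,0.13257,2.0132
33,1.5612,0.1637,0.12627,1.8512
34,1.4236,0.16349,0.12042,1.7075
35,1.3016,0.16325,0.11496,1.5798
36,1.1929,0.163,0.10987,1.4658
37,1.0958,0.16274,0.10512,1.3636
38,1.0088,0.16247,0.10066,1.2719
39,0.93066,0.16218,0.096489,1.1893
40,0.86026,0.16188,0.09257,1.1147
41,0.79668,0.16157,0.088886,1.0471
42,0.73912,0.16126,0.085419,0.9858
43,0.68689,0.16094,0.082151,0.92998
44,0.63939,0.16061,0.079067,0.87907
45,0.5961,0.16028,0.076154,0.83253
46,0.55657,0.15994,0.0734,0.78991
47,0.52041,0.15959,0.070793,0.75079
48,0.48726,0.15925,0.068322,0.71483
49,0.45681,0.1589,0.065979,0.68169
50,0.42882,0.15854,0.063754,0.65111
51,0.40302,0.15819,0.06164,0.62285
52,0.37922,0.15783,0.05963,0.59668
53,0.35722,0.15747,0.057716,0.57241
54,0.33686,0.15711,0.055893,0.54987
55,0.318,0.15675,0.054155,0.5289
56,0.30049,0.15639,0.052498,0.50937
57,0.28422,0.15602,0.050915,0.49116
58,0.26908,0.15566,0.049402,0.47414
59,0.25498,0.1553,0.047956,0.45823
60,0.24183,0.15493,0.046573,0.44333
61,0.22955,0.15457,0.045248,0.42937
62,0.21808,0.1542,0.043979,0.41626
63,0.20734,0.15384,0.042763,0.40394
64,0.19728,0.15348,0.041597,0.39235
65,0.18785,0.15311,0.040478,0.38144
66,0.179,0.15275,0.039403,0.37116
67,0.17069,0.15239,0.03837,0.36145
68,0.16287,0.15203,0.037378,0.35228
69,0.15551,0.15167,0.036423,0.34361
70,0.14859,0.15131,0.035505,0.3354
71,0.14206,0.15096,0.034621,0.32763
72,0.13589,0.1506,0.033769,0.32026
73,0.13008,0.15025,0.032949,0.31327
74,0.12458,0.14989,0.032158,0.30663
75,0.11938,0.14954,0.031395,0.30032
76,0.11446,0.14919,0.030659,0.29431
77,0.10981,0.14884,0.029948,0.2886
78,0.10539,0.14849,0.029262,0.28315
79,0.10121,0.14815,0.028599,0.27796
80,0.097239,0.1478,0.027959,0.273
81,0.093469,0.14746,0.027339,0.26827
82,0.089887,0.14712,0.02674,0.26374
83,0.086482,0.14678,0.026161,0.25942
84,0.083243,0.14644,0.0256,0.25528
85,0.080161,0.1461,0.025057,0.25132
86,0.077226,0.14577,0.024531,0.24752
87,0.074429,0.14543,0.024021,0.24388
88,0.071762,0.1451,0.023527,0.24039
89,0.069219,0.14477,0.023048,0.23704
90,0.066792,0.14444,0.022583,0.23382
91,0.064474,0.14411,0.022133,0.23072
92,0.062261,0.14379,0.021696,0.22774
93,0.060145,0.14346,0.021271,0.22488
94,0.058121,0.14314,0.020859,0.22212
95,0.056186,0.14282,0.020459,0.21947
96,0.054334,0.1425,0.02007,0.21691
97,0.05256,0.14219,0.019692,0.21444
98,0.050861,0.14187,0.019324,0.21206
99,0.049232,0.14156,0.018967,0.20976
100,0.047671,0.14124,0.01862,0.20754
101,0.046174,0.14093,0.018282,0.20539
102,0.044737,0.14063,0.017953,0.20332
103,0.043358,0.14032,0.017633,0.20131
104,0.042034,0.14001,0.017321,0.19937
105,0.040762,0.13971,0.017018,0.19749
106,0.03954,0.13941,0.016722,0.19567
107,0.038364,0.13911,0.016434,0.1939
108,0.037234,0.13881,0.016153,0.19219
109,0.036147,0.13851,0.01588,0.19054
110,0.0351,0.13821,0.015613,0.18893
111,0.034093,0.13792,0.015353,0.18737
112,0.033123,0.13763,0.0151,0.18585
113,0.032189,0.13734,0.014852,0.18438
114,0.031288,0.13705,0.014611,0.18295
115,0.03042,0.13676,0.014376,0.18156
116,0.029583,0.13647,0.014146,0.1802
117,0.028776,0.13619,0.013921,0.17889
118,0.027997,0.13591,0.013702,0.1776
119,0.027245,0.13562,0.013488,0.17636
120,0.02652,0.13534,0.013279,0.17514
121,0.025819,0.13507,0.013075,0.17396
122,0.025142,0.13479,0.012875,0.17281
123,0.024488,0.13451,0.01268,0.17168
124,0.023856,0.13424,0.012489,0.17059
125,0.023245,0.13397,0.012303,0.16952
126,0.022654,0.1337,0.012121,0.16847
127,0.022083,0.13343,0.011942,0.16745
128,0.02153,0.13316,0.011768,0.16646
129,0.020995,0.13289,0.011597,0.16548
130,0.020477,0.13263,0.011431,0.16453
131,0.019975,0.13236,0.011267,0.16361
132,0.01949,0.1321,0.011107,0.1627
133,0.019019,0.13184,0.010951,0.16181
134,0.018564,0.13158,0.010797,0.16094
135,0.018122,0.13132,0.010647,0.16009
136,0.017694,0.13107,0.0105,0.15926
137,0.017279,0.13081,0.010356,0.15845
138,0.016876,0.13056,0.010215,0.15765
139,0.016486,0.1303,0.010077,0.15687
140,0.016107,0.13005,0.0099419,0.1561
141,0.015739,0.1298,0.0098092,0.15535
142,0.015382,0.12955,0.0096791,0.15462
143,0.015036,0.12931,0.0095516,0.15389
144,0.0147,0.12906,0.0094266,0.15319
145,0.014373,0.12882,0.009304,0.15249
146,0.014056,0.12857,0.0091838,0.15181
147,0.013748,0.12833,0.0090659,0.15114
148,0.013448,0.12809,0.0089502,0.15049
149,0.013157,0.12785,0.0088368,0.14984
150,0.012874,0.12761,0.0087254,0.14921
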