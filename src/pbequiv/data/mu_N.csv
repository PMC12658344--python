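energy_keV,photoelectric,incoherent,coherent,total
1,3169.3,0.035027,1.155,3170.5
2,452.27,0.075493,0.86785,453.22
3,137.91,0.10221,0.67589,138.69
4,58.101,0.12077,0.54059,58.763
5,29.447,0.13421,0.44095,30.022
6,16.801,0.14413,0.36585,17.311
7,10.411,0.15156,0.30824,10.871
8,6.8559,0.1572,0.2633,7.2764
9,4.7314,0.16151,0.22765,5.1206
10,3.3831,0.16486,0.19893,3.7468
11,2.496,0.16746,0.17545,2.8389
12,1.8899,0.1695,0.15601,2.2154
13,1.4625,0.1711,0.13972,1.7733
14,1.153,0.17236,0.12593,1.4513
15,0.92379,0.17334,0.11413,1.2113
16,0.75057,0.1741,0.10396,1.0286
17,0.61739,0.17467,0.095115,0.88718
18,0.51343,0.1751,0.08738,0.77591
19,0.43117,0.1754,0.080568,0.68713
20,0.36527,0.1756,0.074537,0.6154
21,0.31191,0.17571,0.069168,0.55678
22,0.26827,0.17574,0.064366,0.50838
23,0.23225,0.17572,0.060054,0.46802
24,0.20228,0.17563,0.056165,0.43408
25,0.17715,0.17551,0.052645,0.40531
26,0.15594,0.17534,0.049449,0.38073
27,0.13787,0.17514,0.046537,0.35954
28,0.12233,0.17491,0.043876,0.34111
29,0.109,0.17465,0.041438,0.32509
30,0.097496,0.17437,0.039199,0.31107
31,0.087529,0.17407,0.037137,0.29874
32,0.078849,0.17376,0.035234,0.28784
33,0.071258,0.17342,0.033474,0.27816
34,0.064592,0.17308,0.031843,0.26952
35,0.058716,0.17272,0.030328,0.26177
36,0.053518,0.17236,0.02892,0.2548
37,0.048904,0.17198,0.027607,0.2485
38,0.044795,0.1716,0.026382,0.24278
39,0.041125,0.17121,0.025236,0.23758
40,0.037837,0.17082,0.024164,0.23282
41,0.034883,0.17042,0.023158,0.22846
42,0.032223,0.17002,0.022215,0.22446
43,0.029821,0.16961,0.021327,0.22076
44,0.027647,0.1692,0.020492,0.21734
45,0.025676,0.16879,0.019705,0.21417
46,0.023883,0.16838,0.018962,0.21123
47,0.02225,0.16797,0.018261,0.20848
48,0.02076,0.16755,0.017598,0.20591
49,0.019397,0.16713,0.01697,0.2035
50,0.018148,0.16672,0.016375,0.20124
51,0.017003,0.1663,0.015811,0.19911
52,0.015949,0.16588,0.015276,0.19711
53,0.014979,0.16546,0.014767,0.19521
54,0.014085,0.16505,0.014283,0.19342
55,0.013259,0.16463,0.013823,0.19171
56,0.012494,0.16422,0.013385,0.1901
57,0.011787,0.1638,0.012967,0.18856
58,0.01113,0.16339,0.012568,0.18709
59,0.010521,0.16298,0.012187,0.18569
60,0.0099539,0.16257,0.011824,0.18434
61,0.0094262,0.16216,0.011476,0.18306
62,0.0089344,0.16175,0.011144,0.18183
63,0.0084755,0.16134,0.010825,0.18064
64,0.0080469,0.16094,0.010521,0.1795
65,0.007646,0.16053,0.010228,0.17841
66,0.0072708,0.16013,0.0099482,0.17735
67,0.0069192,0.15973,0.0096793,0.17633
68,0.0065894,0.15933,0.0094212,0.17534
69,0.0062798,0.15894,0.0091733,0.17439
70,0.0059889,0.15854,0.008935,0.17347
71,0.0057153,0.15815,0.0087058,0.17257
72,0.0054578,0.15776,0.0084854,0.1717
73,0.0052151,0.15737,0.0082732,0.17086
74,0.0049864,0.15699,0.0080688,0.17004
75,0.0047705,0.1566,0.0078719,0.16924
76,0.0045666,0.15622,0.0076821,0.16847
77,0.004374,0.15584,0.0074991,0.16771
78,0.0041918,0.15546,0.0073225,0.16697
79,0.0040193,0.15508,0.0071521,0.16625
80,0.003856,0.15471,0.0069875,0.16555
81,0.0037012,0.15434,0.0068286,0.16487
82,0.0035545,0.15397,0.006675,0.1642
83,0.0034152,0.1536,0.0065265,0.16354
84,0.0032829,0.15323,0.0063829,0.1629
85,0.0031572,0.15287,0.0062439,0.16227
86,0.0030377,0.15251,0.0061095,0.16165
87,0.0029241,0.15215,0.0059793,0.16105
88,0.0028159,0.15179,0.0058532,0.16046
89,0.0027129,0.15143,0.0057311,0.15988
90,0.0026147,0.15108,0.0056128,0.15931
91,0.0025211,0.15073,0.005498,0.15875
92,0.0024318,0.15038,0.0053868,0.1582
93,0.0023466,0.15003,0.0052788,0.15766
94,0.0022653,0.14969,0.0051741,0.15712
95,0.0021875,0.14934,0.0050724,0.1566
96,0.0021133,0.149,0.0049738,0.15609
97,0.0020422,0.14866,0.0048779,0.15558
98,0.0019743,0.14832,0.0047848,0.15508
99,0.0019092,0.14799,0.0046943,0.15459
100,0.0018469,0.14765,0.0046064,0.15411
101,0.0017873,0.14732,0.0045209,0.15363
102,0.0017301,0.14699,0.0044377,0.15316
103,0.0016753,0.14667,0.0043568,0.1527
104,0.0016227,0.14634,0.0042781,0.15224
105,0.0015723,0.14602,0.0042015,0.15179
106,0.0015239,0.14569,0.004127,0.15134
107,0.0014774,0.14537,0.0040544,0.15091
108,0.0014327,0.14506,0.0039837,0.15047
109,0.0013898,0.14474,0.0039148,0.15004
110,0.0013485,0.14442,0.0038477,0.14962
111,0.0013088,0.14411,0.0037822,0.1492
112,0.0012706,0.1438,0.0037185,0.14879
113,0.0012339,0.14349,0.0036563,0.14838
114,0.0011985,0.14318,0.0035957,0.14798
115,0.0011645,0.14288,0.0035366,0.14758
116,0.0011316,0.14258,0.0034789,0.14719
117,0.0011,0.14227,0.0034226,0.1468
118,0.0010695,0.14197,0.0033676,0.14641
119,0.0010402,0.14167,0.003314,0.14603
120,0.0010118,0.14138,0.0032616,0.14565
121,0.00098447,0.14108,0.0032105,0.14528
122,0.00095808,0.14079,0.0031605,0.14491
123,0.0009326,0.1405,0.0031117,0.14454
124,0.000908,0.14021,0.003064,0.14418
125,0.00088424,0.13992,0.0030174,0.14382
126,0.00086127,0.13963,0.0029719,0.14347
127,0.00083908,0.13935,0.0029274,0.14311
128,0.00081763,0.13906,0.0028838,0.14276
129,0.00079689,0.13878,0.0028412,0.14242
130,0.00077682,0.1385,0.0027996,0.14208
131,0.00075741,0.13822,0.0027589,0.14174
132,0.00073863,0.13795,0.002719,0.1414
133,0.00072045,0.13767,0.00268,0.14107
134,0.00070284,0.1374,0.0026418,0.14074
135,0.00068579,0.13712,0.0026045,0.14041
136,0.00066928,0.13685,0.0025679,0.14009
137,0.00065328,0.13658,0.0025321,0.13977
138,0.00063778,0.13631,0.002497,0.13945
139,0.00062275,0.13605,0.0024626,0.13913
140,0.00060818,0.13578,0.002429,0.13882
141,0.00059405,0.13552,0.002396,0.13851
142,0.00058034,0.13526,0.0023637,0.1382
143,0.00056704,0.135,0.002332,0.13789
144,0.00055414,0.13474,0.002301,0.13759
145,0.00054161,0.13448,0.0022706,0.13729
146,0.00052946,0.13422,0.0022408,0.13699
147,0.00051765,0.13397,0.0022115,0.1367
148,0.00050619,0.13371,0.0021829,0.1364
149,0.00049505,0.13346,0.0021547,0.13611
150,0.00048423,0.13321,0.0021272,0.13582
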