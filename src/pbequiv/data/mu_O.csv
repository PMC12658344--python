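energy_keV,photoelectric,incoherent,coherent,total
1,4419.2,0.032944,1.3377,4420.5
2,664.02,0.072615,1.0159,665.1
3,206.78,0.099276,0.79713,207.67
4,88.274,0.11794,0.6417,89.033
5,45.185,0.13158,0.52629,45.843
6,25.984,0.14174,0.43858,26.564
7,16.206,0.14941,0.3708,16.726
8,10.732,0.15527,0.31761,11.205
9,7.4421,0.15979,0.27522,7.8771
10,5.3536,0.16331,0.24094,5.7578
11,3.9624,0.16607,0.21284,4.3413
12,3.0087,0.16825,0.18951,3.3664
13,2.3342,0.16997,0.16992,2.6741
14,1.8445,0.17133,0.15331,2.1691
15,1.4808,0.1724,0.13908,1.7923
16,1.2054,0.17323,0.1268,1.5054
17,0.99325,0.17388,0.11611,1.2832
18,0.82732,0.17437,0.10675,1.1084
19,0.6958,0.17473,0.098502,0.96903
20,0.59028,0.17497,0.091191,0.85644
21,0.5047,0.17513,0.084678,0.7645
22,0.4346,0.17521,0.078849,0.68866
23,0.37668,0.17522,0.07361,0.62551
24,0.32842,0.17517,0.068882,0.57248
25,0.28792,0.17508,0.0646,0.52759
26,0.25368,0.17494,0.060708,0.48933
27,0.22448,0.17476,0.057161,0.4564
28,0.19934,0.17456,0.053918,0.42781
29,0.17775,0.17432,0.050945,0.40302
30,0.15911,0.17406,0.048212,0.38139
31,0.14294,0.17378,0.045695,0.36242
32,0.12886,0.17348,0.04337,0.34571
33,0.11653,0.17317,0.041219,0.33091
34,0.10569,0.17284,0.039225,0.31775
35,0.096132,0.1725,0.037372,0.306
36,0.087672,0.17215,0.035647,0.29547
37,0.080157,0.17179,0.03404,0.28598
38,0.07346,0.17142,0.032539,0.27741
39,0.067475,0.17104,0.031135,0.26965
40,0.062111,0.17065,0.02982,0.26259
41,0.057289,0.17027,0.028587,0.25614
42,0.052945,0.16987,0.027429,0.25025
43,0.04902,0.16948,0.02634,0.24484
44,0.045466,0.16907,0.025314,0.23986
45,0.042241,0.16867,0.024347,0.23526
46,0.039308,0.16827,0.023435,0.23101
47,0.036634,0.16786,0.022573,0.22707
48,0.034193,0.16745,0.021758,0.2234
49,0.03196,0.16704,0.020986,0.21998
50,0.029914,0.16663,0.020254,0.2168
51,0.028034,0.16622,0.01956,0.21381
52,0.026306,0.1658,0.018901,0.21101
53,0.024715,0.16539,0.018275,0.20838
54,0.023246,0.16498,0.017679,0.20591
55,0.021889,0.16457,0.017112,0.20357
56,0.020634,0.16416,0.016572,0.20136
57,0.019471,0.16375,0.016057,0.19928
58,0.018392,0.16334,0.015565,0.1973
59,0.017389,0.16293,0.015096,0.19542
60,0.016457,0.16252,0.014648,0.19363
61,0.015588,0.16212,0.014219,0.19192
62,0.014779,0.16171,0.013809,0.1903
63,0.014023,0.16131,0.013416,0.18875
64,0.013317,0.16091,0.01304,0.18726
65,0.012657,0.16051,0.01268,0.18584
66,0.012039,0.16011,0.012334,0.18448
67,0.011459,0.15971,0.012002,0.18317
68,0.010915,0.15931,0.011683,0.18191
69,0.010405,0.15892,0.011377,0.1807
70,0.0099249,0.15853,0.011083,0.17954
71,0.0094735,0.15814,0.010799,0.17841
72,0.0090485,0.15775,0.010527,0.17733
73,0.0086479,0.15736,0.010265,0.17628
74,0.0082702,0.15698,0.010012,0.17526
75,0.0079137,0.1566,0.0097689,0.17428
76,0.0075769,0.15622,0.0095343,0.17333
77,0.0072586,0.15584,0.009308,0.1724
78,0.0069575,0.15546,0.0090896,0.17151
79,0.0066724,0.15509,0.0088788,0.17064
80,0.0064024,0.15471,0.0086753,0.16979
81,0.0061465,0.15434,0.0084786,0.16897
82,0.0059037,0.15397,0.0082886,0.16817
83,0.0056733,0.15361,0.0081049,0.16739
84,0.0054544,0.15324,0.0079272,0.16663
85,0.0052464,0.15288,0.0077552,0.16588
86,0.0050487,0.15252,0.0075888,0.16516
87,0.0048605,0.15216,0.0074277,0.16445
88,0.0046814,0.15181,0.0072716,0.16376
89,0.0045108,0.15145,0.0071204,0.16308
90,0.0043481,0.1511,0.0069738,0.16242
91,0.0041931,0.15075,0.0068317,0.16177
92,0.0040452,0.1504,0.0066939,0.16114
93,0.003904,0.15005,0.0065602,0.16052
94,0.0037691,0.14971,0.0064305,0.15991
95,0.0036403,0.14937,0.0063046,0.15931
96,0.0035171,0.14903,0.0061823,0.15872
97,0.0033993,0.14869,0.0060635,0.15815
98,0.0032866,0.14835,0.0059481,0.15758
99,0.0031787,0.14802,0.005836,0.15703
100,0.0030754,0.14768,0.005727,0.15648
101,0.0029764,0.14735,0.005621,0.15595
102,0.0028815,0.14702,0.0055179,0.15542
103,0.0027905,0.1467,0.0054177,0.1549
104,0.0027033,0.14637,0.0053201,0.15439
105,0.0026195,0.14605,0.0052251,0.15389
106,0.0025391,0.14573,0.0051327,0.1534
107,0.0024619,0.14541,0.0050426,0.15291
108,0.0023877,0.14509,0.0049549,0.15243
109,0.0023164,0.14477,0.0048695,0.15196
110,0.0022479,0.14446,0.0047862,0.15149
111,0.0021819,0.14415,0.0047051,0.15103
112,0.0021185,0.14384,0.004626,0.15058
113,0.0020574,0.14353,0.0045489,0.15013
114,0.0019986,0.14322,0.0044737,0.14969
115,0.001942,0.14292,0.0044003,0.14926
116,0.0018875,0.14261,0.0043287,0.14883
117,0.0018349,0.14231,0.0042588,0.14841
118,0.0017842,0.14201,0.0041906,0.14799
119,0.0017354,0.14171,0.0041241,0.14757
120,0.0016882,0.14142,0.0040591,0.14716
121,0.0016427,0.14112,0.0039956,0.14676
122,0.0015988,0.14083,0.0039336,0.14636
123,0.0015565,0.14054,0.003873,0.14597
124,0.0015155,0.14025,0.0038138,0.14558
125,0.001476,0.13996,0.0037559,0.14519
126,0.0014378,0.13967,0.0036994,0.14481
127,0.0014008,0.13939,0.0036441,0.14443
128,0.0013651,0.13911,0.00359,0.14406
129,0.0013306,0.13882,0.0035372,0.14369
130,0.0012972,0.13854,0.0034854,0.14333
131,0.0012649,0.13827,0.0034348,0.14297
132,0.0012336,0.13799,0.0033853,0.14261
133,0.0012033,0.13771,0.0033369,0.14225
134,0.001174,0.13744,0.0032895,0.1419
135,0.0011456,0.13717,0.0032431,0.14156
136,0.0011181,0.1369,0.0031976,0.14121
137,0.0010914,0.13663,0.0031531,0.14087
138,0.0010656,0.13636,0.0031095,0.14054
139,0.0010406,0.13609,0.0030668,0.1402
140,0.0010163,0.13583,0.003025,0.13987
141,0.00099274,0.13557,0.0029841,0.13954
142,0.0009699,0.1353,0.0029439,0.13922
143,0.00094774,0.13504,0.0029046,0.1389
144,0.00092623,0.13478,0.002866,0.13858
145,0.00090535,0.13453,0.0028282,0.13826
146,0.00088508,0.13427,0.0027911,0.13795
147,0.0008654,0.13401,0.0027548,0.13763
148,0.00084628,0.13376,0.0027192,0.13733
149,0.00082771,0.13351,0.0026842,0.13702
150,0.00080967,0.13326,0.0026499,0.13672
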