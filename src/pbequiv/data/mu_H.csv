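energy_keV,photoelectric,incoherent,coherent,total
1,1e-12,0.14477,0.25195,0.39673
2,1e-12,0.23613,0.15914,0.39527
3,1e-12,0.28488,0.10877,0.39365
4,1e-12,0.31326,0.078766,0.39202
5,1e-12,0.33068,0.059752,0.39043
6,1e-12,0.34187,0.046999,0.38887
7,1e-12,0.34933,0.038021,0.38735
8,1e-12,0.35441,0.031446,0.38585
9,1e-12,0.35791,0.026474,0.38438
10,1e-12,0.36031,0.022615,0.38293
11,1e-12,0.36194,0.019555,0.3815
12,1e-12,0.363,0.017083,0.38008
13,1e-12,0.36363,0.015056,0.37869
14,1e-12,0.36393,0.013372,0.3773
15,1e-12,0.36398,0.011957,0.37594
16,1e-12,0.36383,0.010756,0.37459
17,1e-12,0.36352,0.0097277,0.37325
18,1e-12,0.36309,0.0088405,0.37193
19,1e-12,0.36255,0.0080696,0.37062
20,1e-12,0.36193,0.0073954,0.36932
21,1e-12,0.36124,0.0068024,0.36804
22,1e-12,0.36049,0.0062779,0.36677
23,1e-12,0.3597,0.0058119,0.36551
24,1e-12,0.35887,0.0053959,0.36426
25,1e-12,0.358,0.005023,0.36303
26,1e-12,0.35712,0.0046874,0.3618
27,1e-12,0.35621,0.0043844,0.36059
28,1e-12,0.35528,0.0041098,0.35939
29,1e-12,0.35434,0.0038602,0.3582
30,1e-12,0.35339,0.0036327,0.35702
31,1e-12,0.35243,0.0034247,0.35585
32,1e-12,0.35146,0.003234,0.35469
33,1e-12,0.35049,0.0030588,0.35355
34,1e-12,0.34951,0.0028974,0.35241
35,1e-12,0.34853,0.0027485,0.35128
36,1e-12,0.34755,0.0026107,0.35016
37,1e-12,0.34657,0.002483,0.34906
38,1e-12,0.34559,0.0023645,0.34796
39,1e-12,0.34462,0.0022542,0.34687
40,1e-12,0.34364,0.0021515,0.34579
41,1e-12,0.34267,0.0020556,0.34472
42,1e-12,0.34169,0.0019659,0.34366
43,1e-12,0.34073,0.001882,0.34261
44,1e-12,0.33976,0.0018034,0.34156
45,1e-12,0.3388,0.0017295,0.34053
46,1e-12,0.33784,0.0016601,0.3395
47,1e-12,0.33689,0.0015948,0.33849
48,1e-12,0.33594,0.0015332,0.33748
49,1e-12,0.335,0.0014751,0.33648
50,1e-12,0.33406,0.0014203,0.33548
51,1e-12,0.33313,0.0013684,0.3345
52,1e-12,0.3322,0.0013194,0.33352
53,1e-12,0.33128,0.0012729,0.33255
54,1e-12,0.33036,0.0012288,0.33159
55,1e-12,0.32945,0.001187,0.33064
56,1e-12,0.32855,0.0011473,0.32969
57,1e-12,0.32765,0.0011095,0.32876
58,1e-12,0.32675,0.0010735,0.32783
59,1e-12,0.32586,0.0010393,0.3269
60,1e-12,0.32498,0.0010066,0.32599
61,1e-12,0.3241,0.00097553,0.32508
62,1e-12,0.32323,0.00094582,0.32417
63,1e-12,0.32236,0.00091745,0.32328
64,1e-12,0.3215,0.00089033,0.32239
65,1e-12,0.32065,0.00086439,0.32151
66,1e-12,0.3198,0.00083956,0.32064
67,1e-12,0.31895,0.00081579,0.31977
68,1e-12,0.31811,0.00079301,0.31891
69,1e-12,0.31728,0.00077116,0.31805
70,1e-12,0.31645,0.00075021,0.3172
71,1e-12,0.31563,0.00073009,0.31636
72,1e-12,0.31481,0.00071077,0.31552
73,1e-12,0.314,0.00069221,0.31469
74,1e-12,0.3132,0.00067435,0.31387
75,1e-12,0.31239,0.00065718,0.31305
76,1e-12,0.3116,0.00064066,0.31224
77,1e-12,0.31081,0.00062475,0.31143
78,1e-12,0.31002,0.00060942,0.31063
79,1e-12,0.30925,0.00059464,0.30984
80,1e-12,0.30847,0.0005804,0.30905
81,1e-12,0.3077,0.00056666,0.30827
82,1e-12,0.30694,0.0005534,0.30749
83,1e-12,0.30618,0.0005406,0.30672
84,1e-12,0.30542,0.00052824,0.30595
85,1e-12,0.30468,0.00051629,0.30519
86,1e-12,0.30393,0.00050475,0.30444
87,1e-12,0.30319,0.00049358,0.30369
88,1e-12,0.30246,0.00048278,0.30294
89,1e-12,0.30173,0.00047233,0.3022
90,1e-12,0.301,0.00046222,0.30147
91,1e-12,0.30028,0.00045242,0.30074
92,1e-12,0.29957,0.00044294,0.30001
93,1e-12,0.29886,0.00043374,0.29929
94,1e-12,0.29815,0.00042483,0.29858
95,1e-12,0.29745,0.00041619,0.29787
96,1e-12,0.29676,0.00040781,0.29716
97,1e-12,0.29606,0.00039968,0.29646
98,1e-12,0.29537,0.00039179,0.29577
99,1e-12,0.29469,0.00038413,0.29508
100,1e-12,0.29401,0.0003767,0.29439
101,1e-12,0.29334,0.00036947,0.29371
102,1e-12,0.29267,0.00036245,0.29303
103,1e-12,0.292,0.00035563,0.29236
104,1e-12,0.29134,0.000349,0.29169
105,1e-12,0.29068,0.00034255,0.29102
106,1e-12,0.29003,0.00033628,0.29036
107,1e-12,0.28938,0.00033018,0.28971
108,1e-12,0.28873,0.00032424,0.28906
109,1e-12,0.28809,0.00031846,0.28841
110,1e-12,0.28745,0.00031284,0.28777
111,1e-12,0.28682,0.00030736,0.28713
112,1e-12,0.28619,0.00030202,0.28649
113,1e-12,0.28557,0.00029682,0.28586
114,1e-12,0.28494,0.00029175,0.28524
115,1e-12,0.28433,0.00028682,0.28461
116,1e-12,0.28371,0.000282,0.28399
117,1e-12,0.2831,0.00027731,0.28338
118,1e-12,0.2825,0.00027273,0.28277
119,1e-12,0.28189,0.00026826,0.28216
120,1e-12,0.28129,0.0002639,0.28156
121,1e-12,0.2807,0.00025965,0.28096
122,1e-12,0.28011,0.0002555,0.28036
123,1e-12,0.27952,0.00025145,0.27977
124,1e-12,0.27893,0.00024749,0.27918
125,1e-12,0.27835,0.00024363,0.27859
126,1e-12,0.27777,0.00023985,0.27801
127,1e-12,0.2772,0.00023616,0.27743
128,1e-12,0.27663,0.00023256,0.27686
129,1e-12,0.27606,0.00022903,0.27629
130,1e-12,0.27549,0.00022559,0.27572
131,1e-12,0.27493,0.00022222,0.27515
132,1e-12,0.27437,0.00021893,0.27459
133,1e-12,0.27382,0.00021571,0.27403
134,1e-12,0.27327,0.00021256,0.27348
135,1e-12,0.27272,0.00020948,0.27293
136,1e-12,0.27217,0.00020647,0.27238
137,1e-12,0.27163,0.00020352,0.27184
138,1e-12,0.27109,0.00020063,0.27129
139,1e-12,0.27056,0.0001978,0.27075
140,1e-12,0.27002,0.00019504,0.27022
141,1e-12,0.26949,0.00019233,0.26969
142,1e-12,0.26897,0.00018967,0.26916
143,1e-12,0.26844,0.00018707,0.26863
144,1e-12,0.26792,0.00018452,0.26811
145,1e-12,0.2674,0.00018203,0.26759
146,1e-12,0.26689,0.00017958,0.26707
147,1e-12,0.26638,0.00017719,0.26655
148,1e-12,0.26587,0.00017484,0.26604
149,1e-12,0.26536,0.00017254,0.26553
150,1e-12,0.26486,0.00017028,0.26503
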