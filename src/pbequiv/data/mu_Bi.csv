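energy_keV,photoelectric,incoherent,coherent,total
1,5223.1,0.007277,12.599,5235.7
2,1288.3,0.022982,11.279,1299.6
2.5796,738.02,0.032493,10.474,748.53
2.5796,9361.3,0.032557,10.468,9371.8
3,2020.6,0.039043,9.9162,2030.6
4,1270.4,0.052704,8.7452,1279.2
5,738.84,0.06392,7.7725,746.68
6,469.62,0.073194,6.9581,476.65
7,318.5,0.080969,6.2659,324.85
8,226.77,0.087567,5.67,232.53
9,167.66,0.093211,5.1522,172.9
10,127.63,0.098065,4.6994,132.43
11,99.655,0.10226,4.3014,104.06
12,79.445,0.10588,3.9502,83.501
13,64.455,0.10903,3.6393,68.203
13.4186,59.349,0.11021,3.5203,62.98
13.4186,151.78,0.11022,3.5192,155.41
14,135.39,0.11175,3.3631,138.87
15,112.21,0.11413,3.1169,115.44
15.7111,98.897,0.11562,2.9583,101.97
15.7111,138.78,0.11563,2.9575,141.85
16,132.21,0.11619,2.8967,135.23
16.3875,124.03,0.11692,2.8181,126.96
16.3875,143.34,0.11692,2.8173,146.27
17,130.67,0.11799,2.6993,133.49
18,112.88,0.11956,2.5215,115.53
19,98.224,0.12093,2.3611,100.71
20,86.041,0.12212,2.2157,88.379
21,75.825,0.12316,2.0838,78.032
22,67.192,0.12407,1.9635,69.279
23,59.842,0.12485,1.8537,61.821
24,53.543,0.12553,1.7531,55.422
25,48.111,0.12612,1.6607,49.897
26,43.399,0.12663,1.5757,45.102
27,39.286,0.12706,1.4972,40.911
28,35.672,0.12743,1.4246,37.224
29,32.497,0.12774,1.3574,33.982
30,29.693,0.128,1.2949,31.116
31,27.209,0.12821,1.2368,28.574
32,24.996,0.12837,1.1827,26.307
33,23.017,0.1285,1.1321,24.278
34,21.243,0.1286,1.0848,22.456
35,19.65,0.12867,1.0404,20.819
36,18.215,0.1287,0.99886,19.342
37,16.918,0.12871,0.95977,18.007
38,15.745,0.1287,0.923,16.796
39,14.679,0.12867,0.88834,15.696
40,13.709,0.12862,0.85565,14.693
41,12.824,0.12855,0.82477,13.777
42,12.014,0.12846,0.79556,12.938
43,11.273,0.12836,0.76791,12.169
44,10.592,0.12825,0.7417,11.462
45,9.9665,0.12812,0.71683,10.811
46,9.3897,0.12798,0.69322,10.211
47,8.8572,0.12783,0.67077,9.6558
48,8.3649,0.12768,0.64941,9.142
49,7.909,0.12751,0.62907,8.6656
50,7.4861,0.12734,0.60968,8.2232
51,7.0933,0.12716,0.59119,7.8117
52,6.728,0.12697,0.57354,7.4285
53,6.3876,0.12678,0.55667,7.0711
54,6.0702,0.12658,0.54054,6.7374
55,5.7738,0.12637,0.52512,6.4253
56,5.4967,0.12617,0.51035,6.1332
57,5.2372,0.12595,0.4962,5.8594
58,4.9941,0.12574,0.48263,5.6024
59,4.7657,0.12552,0.46962,5.3609
60,4.5513,0.12529,0.45713,5.1337
61,4.3497,0.12507,0.44513,4.9199
62,4.1601,0.12484,0.43361,4.7185
63,3.9814,0.12461,0.42253,4.5286
64,3.813,0.12437,0.41187,4.3493
65,3.6542,0.12414,0.40161,4.1799
66,3.5041,0.1239,0.39173,4.0197
67,3.3623,0.12366,0.38221,3.8681
68,3.2281,0.12342,0.37304,3.7246
69,3.101,0.12318,0.36419,3.5884
70,2.9807,0.12294,0.35566,3.4593
71,2.8665,0.1227,0.34742,3.3366
72,2.7581,0.12245,0.33947,3.22
73,2.6552,0.12221,0.33179,3.1092
74,2.5575,0.12196,0.32437,3.0038
75,2.4645,0.12172,0.31719,2.9035
76,2.3762,0.12147,0.31025,2.8079
77,2.292,0.12123,0.30354,2.7168
78,2.2119,0.12098,0.29704,2.6299
79,2.1355,0.12074,0.29075,2.547
80,2.0627,0.12049,0.28465,2.4678
81,1.9932,0.12024,0.27875,2.3922
82,1.9268,0.12,0.27303,2.3199
83,1.8634,0.11975,0.26748,2.2507
84,1.8029,0.11951,0.2621,2.1845
85,1.7449,0.11926,0.25688,2.1211
86,1.6895,0.11902,0.25182,2.0603
87,1.6364,0.11877,0.2469,2.0021
88,1.5856,0.11853,0.24213,1.9462
89,1.5369,0.11828,0.2375,1.8927
90,1.4902,0.11804,0.23299,1.8412
90.526,1.4665,0.11791,0.23068,1.8151
90.526,6.9301,0.11791,0.23067,7.2787
91,6.8392,0.1178,0.22862,7.1856
92,6.6519,0.11756,0.22436,6.9938
93,6.4715,0.11732,0.22022,6.809
94,6.2976,0.11708,0.2162,6.6308
95,6.1299,0.11684,0.21229,6.459
96,5.9682,0.1166,0.20848,6.2933
97,5.8122,0.11636,0.20477,6.1333
98,5.6617,0.11612,0.20116,5.9789
99,5.5163,0.11589,0.19765,5.8298
100,5.3759,0.11565,0.19422,5.6858
101,5.2403,0.11541,0.19089,5.5466
102,5.1093,0.11518,0.18764,5.4121
103,4.9826,0.11495,0.18447,5.2821
104,4.8596,0.11471,0.18138,5.1557
105,4.7405,0.11448,0.17837,5.0334
106,4.6254,0.11425,0.17543,4.9151
107,4.5141,0.11402,0.17257,4.8007
108,4.4063,0.11379,0.16977,4.6899
109,4.3021,0.11356,0.16705,4.5827
110,4.2012,0.11334,0.16438,4.4789
111,4.1035,0.11311,0.16178,4.3784
112,4.0088,0.11289,0.15925,4.2809
113,3.9171,0.11266,0.15677,4.1865
114,3.8283,0.11244,0.15434,4.095
115,3.7421,0.11222,0.15198,4.0063
116,3.6586,0.11199,0.14967,3.9203
117,3.5776,0.11177,0.14741,3.8368
118,3.499,0.11155,0.1452,3.7558
119,3.4228,0.11133,0.14304,3.6771
120,3.3488,0.11112,0.14093,3.6008
121,3.2769,0.1109,0.13886,3.5267
122,3.2071,0.11068,0.13684,3.4547
123,3.1394,0.11047,0.13486,3.3847
124,3.0736,0.11026,0.13293,3.3167
125,3.0096,0.11004,0.13103,3.2507
126,2.9474,0.10983,0.12918,3.1865
127,2.887,0.10962,0.12737,3.124
128,2.8282,0.10941,0.12559,3.0632
129,2.7706,0.1092,0.12385,3.0036
130,2.7145,0.10899,0.12215,2.9456
131,2.66,0.10879,0.12048,2.8892
132,2.6069,0.10858,0.11885,2.8343
133,2.5553,0.10837,0.11724,2.7809
134,2.5051,0.10817,0.11568,2.729
135,2.4563,0.10797,0.11414,2.6784
136,2.4087,0.10776,0.11263,2.6291
137,2.3624,0.10756,0.11115,2.5811
138,2.3173,0.10736,0.1097,2.5344
139,2.2734,0.10716,0.10828,2.4888
140,2.2306,0.10696,0.10689,2.4445
141,2.189,0.10677,0.10552,2.4012
142,2.1483,0.10657,0.10418,2.3591
143,2.1088,0.10637,0.10286,2.318
144,2.0702,0.10618,0.10157,2.2779
145,2.0325,0.10598,0.10031,2.2388
146,1.9958,0.10579,0.099063,2.2007
147,1.9601,0.1056,0.097843,2.1635
148,1.9251,0.10541,0.096645,2.1272
149,1.8911,0.10522,0.095469,2.0918
150,1.8578,0.10503,0.094314,2.0572
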