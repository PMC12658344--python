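energy_keV,photoelectric,incoherent,coherent,total
1,7907.1,0.010444,7.912,7915
2,1602,0.030917,6.875,1608.9
3,587.77,0.049886,5.9051,593.72
3.9288,294.66,0.064102,5.1704,299.89
3.9288,999.4,0.064157,5.1675,1004.6
4,943.93,0.0651,5.1185,949.11
4.1561,840.83,0.067147,5.0119,845.91
4.1561,1168.8,0.067199,5.0092,1173.9
5,831.86,0.077229,4.4836,836.42
6,520.67,0.087084,3.9607,524.72
7,347.9,0.095226,3.5222,351.51
8,244.26,0.10203,3.1501,247.51
9,178.18,0.10775,2.8317,181.12
10,133.94,0.11258,2.5576,136.61
11,103.35,0.11667,2.3204,105.78
12,81.488,0.12015,2.1142,83.722
13,65.437,0.12311,1.9342,67.494
14,53.372,0.12564,1.7762,55.274
15,44.12,0.1278,1.637,45.885
16,36.906,0.12965,1.5138,38.549
17,31.194,0.13123,1.4042,32.73
18,26.607,0.13259,1.3064,28.046
19,22.88,0.13375,1.2188,24.233
20,19.822,0.13474,1.1399,21.097
21,17.289,0.13559,1.0686,18.494
22,15.174,0.13631,1.0041,16.315
23,13.394,0.13693,0.94537,14.476
24,11.884,0.13744,0.89182,12.913
25,10.594,0.13787,0.84284,11.575
26,9.4862,0.13823,0.79791,10.422
27,8.524,0.13852,0.75658,9.4191
28,7.6798,0.13875,0.71847,8.537
29,6.9446,0.13893,0.68325,7.7668
29.2,6.8104,0.13896,0.6766,7.626
29.2,43.309,0.13896,0.67646,44.124
30,40.263,0.13907,0.65063,41.053
31,36.892,0.13916,0.62035,37.651
32,33.943,0.13921,0.59219,34.674
33,31.302,0.13924,0.56594,32.007
34,28.93,0.13923,0.54144,29.611
35,26.794,0.13919,0.51854,27.451
36,24.864,0.13913,0.49708,25.5
37,23.116,0.13905,0.47695,23.732
38,21.528,0.13895,0.45805,22.125
39,20.079,0.13884,0.44026,20.659
40,18.759,0.1387,0.42351,19.321
41,17.552,0.13855,0.40771,18.098
42,16.447,0.13839,0.39278,16.978
43,15.433,0.13822,0.37868,15.95
44,14.502,0.13803,0.36533,15.005
45,13.644,0.13784,0.35268,14.134
46,12.853,0.13763,0.34068,13.331
47,12.122,0.13742,0.32929,12.588
48,11.445,0.1372,0.31847,11.901
49,10.818,0.13697,0.30817,11.263
50,10.236,0.13674,0.29838,10.671
51,9.6954,0.1365,0.28904,10.121
52,9.1921,0.13626,0.28014,9.6085
53,8.723,0.13601,0.27164,9.1306
54,8.2853,0.13576,0.26353,8.6846
55,7.8764,0.1355,0.25578,8.2677
56,7.494,0.13524,0.24837,7.8776
57,7.1359,0.13498,0.24127,7.5121
58,6.8002,0.13471,0.23448,7.1694
59,6.4846,0.13445,0.22797,6.847
60,6.1877,0.13418,0.22173,6.5436
61,5.9088,0.13391,0.21574,6.2585
62,5.6465,0.13363,0.21,5.9901
63,5.3995,0.13336,0.20448,5.7373
64,5.1667,0.13308,0.19917,5.499
65,4.9472,0.13281,0.19407,5.2741
66,4.74,0.13253,0.18916,5.0616
67,4.5442,0.13225,0.18444,4.8609
68,4.359,0.13197,0.17989,4.6709
69,4.1838,0.13169,0.17551,4.491
70,4.0179,0.13141,0.17129,4.3206
71,3.8607,0.13113,0.16722,4.159
72,3.7116,0.13085,0.16329,4.0057
73,3.57,0.13057,0.1595,3.8601
74,3.4356,0.13029,0.15584,3.7217
75,3.3078,0.13001,0.1523,3.5902
76,3.1863,0.12973,0.14888,3.465
77,3.0707,0.12945,0.14558,3.3458
78,2.9606,0.12918,0.14238,3.2322
79,2.8558,0.1289,0.13929,3.1239
80,2.7558,0.12862,0.1363,3.0207
81,2.6593,0.12834,0.13341,2.9211
82,2.5674,0.12807,0.1306,2.8261
83,2.4797,0.12779,0.12789,2.7353
84,2.3959,0.12751,0.12525,2.6487
85,2.316,0.12724,0.1227,2.5659
86,2.2396,0.12697,0.12023,2.4868
87,2.1665,0.12669,0.11783,2.411
88,2.0966,0.12642,0.1155,2.3385
89,2.0297,0.12615,0.11323,2.2691
90,1.9657,0.12588,0.11104,2.2026
91,1.9044,0.12561,0.10891,2.1389
92,1.8456,0.12534,0.10683,2.0777
93,1.7892,0.12507,0.10482,2.0191
94,1.7351,0.12481,0.10286,1.9628
95,1.6832,0.12454,0.10096,1.9087
96,1.6333,0.12428,0.099112,1.8567
97,1.5855,0.12402,0.097312,1.8068
98,1.5395,0.12375,0.095561,1.7588
99,1.4952,0.12349,0.093857,1.7126
100,1.4527,0.12323,0.092197,1.6681
101,1.4118,0.12297,0.090582,1.6253
102,1.3724,0.12272,0.089008,1.5841
103,1.3345,0.12246,0.087475,1.5444
104,1.298,0.1222,0.085981,1.5062
105,1.2628,0.12195,0.084525,1.4693
106,1.2289,0.1217,0.083106,1.4337
107,1.1962,0.12144,0.081722,1.3993
108,1.1646,0.12119,0.080373,1.3662
109,1.1342,0.12094,0.079056,1.3342
110,1.1048,0.1207,0.077772,1.3033
111,1.0765,0.12045,0.076519,1.2734
112,1.0491,0.1202,0.075295,1.2446
113,1.0226,0.11996,0.074101,1.2167
114,0.99706,0.11971,0.072935,1.1897
115,0.97234,0.11947,0.071796,1.1636
116,0.94845,0.11923,0.070684,1.1384
117,0.92533,0.11899,0.069597,1.1139
118,0.90297,0.11875,0.068535,1.0903
119,0.88133,0.11851,0.067497,1.0673
120,0.86038,0.11827,0.066483,1.0451
121,0.8401,0.11804,0.065491,1.0236
122,0.82045,0.1178,0.064521,1.0028
123,0.80142,0.11757,0.063573,0.98256
124,0.78298,0.11734,0.062645,0.96296
125,0.7651,0.1171,0.061737,0.94394
126,0.74777,0.11687,0.060849,0.92549
127,0.73096,0.11665,0.05998,0.90759
128,0.71466,0.11642,0.05913,0.8902
129,0.69884,0.11619,0.058297,0.87333
130,0.68349,0.11596,0.057482,0.85694
131,0.66859,0.11574,0.056683,0.84101
132,0.65412,0.11552,0.055902,0.82554
133,0.64007,0.11529,0.055136,0.8105
134,0.62643,0.11507,0.054386,0.79589
135,0.61317,0.11485,0.053651,0.78167
136,0.60029,0.11463,0.05293,0.76785
137,0.58777,0.11442,0.052225,0.75441
138,0.57559,0.1142,0.051533,0.74132
139,0.56376,0.11398,0.050855,0.72859
140,0.55225,0.11377,0.05019,0.7162
141,0.54105,0.11355,0.049538,0.70414
142,0.53016,0.11334,0.048898,0.6924
143,0.51956,0.11313,0.048271,0.68096
144,0.50924,0.11292,0.047656,0.66981
145,0.49919,0.11271,0.047052,0.65896
146,0.48941,0.1125,0.04646,0.64838
147,0.47989,0.11229,0.045879,0.63806
148,0.47061,0.11209,0.045309,0.62801
149,0.46158,0.11188,0.044749,0.61821
150,0.45277,0.11168,0.0442,0.60865
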