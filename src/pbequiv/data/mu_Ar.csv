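energy_keV,photoelectric,incoherent,coherent,total
1,3056,0.019791,2.8911,3058.9
2,487.07,0.050053,2.3392,489.46
3,160.97,0.073129,1.9138,162.96
3.2029,134.44,0.076947,1.8428,136.36
3.2029,1339,0.077021,1.8415,1341
4,757.59,0.090095,1.597,759.28
5,420.52,0.10303,1.3521,421.98
6,257.22,0.11313,1.1576,258.49
7,168.35,0.12112,1.0008,169.47
8,116.01,0.12751,0.87309,117.02
9,83.239,0.13264,0.76801,84.14
10,61.623,0.13678,0.6808,62.441
11,46.866,0.14015,0.60776,47.614
12,36.45,0.1429,0.54606,37.138
13,28.889,0.14515,0.4935,29.528
14,23.267,0.14699,0.44837,23.862
15,18.988,0.14851,0.40932,19.545
16,15.691,0.14976,0.37531,16.216
17,13.11,0.15078,0.34549,13.607
18,11.062,0.15162,0.3192,11.533
19,9.4163,0.1523,0.29588,9.8645
20,8.0787,0.15285,0.27509,8.5067
21,6.9808,0.15328,0.25648,7.3906
22,6.0714,0.15362,0.23974,6.4647
23,5.3118,0.15387,0.22463,5.6903
24,4.6725,0.15405,0.21094,5.0375
25,4.1308,0.15416,0.19848,4.4834
26,3.6687,0.15423,0.18712,4.0101
27,3.2723,0.15424,0.17673,3.6033
28,2.9303,0.15422,0.16719,3.2517
29,2.6338,0.15415,0.15841,2.9463
30,2.3754,0.15406,0.15032,2.6798
31,2.1494,0.15393,0.14283,2.4461
32,1.9507,0.15378,0.1359,2.2404
33,1.7755,0.15361,0.12947,2.0586
34,1.6203,0.15342,0.12349,1.8972
35,1.4825,0.15321,0.11791,1.7536
36,1.3596,0.15298,0.11271,1.6253
37,1.2497,0.15274,0.10785,1.5103
38,1.1512,0.15249,0.10329,1.407
39,1.0626,0.15222,0.099025,1.3139
40,0.98273,0.15195,0.095016,1.2297
41,0.91054,0.15167,0.091247,1.1534
42,0.84512,0.15138,0.087698,1.0842
43,0.78573,0.15108,0.084353,1.0212
44,0.73167,0.15078,0.081197,0.96365
45,0.68238,0.15047,0.078215,0.91106
46,0.63734,0.15015,0.075394,0.86289
47,0.59611,0.14984,0.072724,0.81867
48,0.55829,0.14951,0.070193,0.778
49,0.52355,0.14919,0.067792,0.74053
50,0.49158,0.14886,0.065513,0.70595
51,0.46211,0.14853,0.063347,0.67399
52,0.43491,0.1482,0.061286,0.64439
53,0.40976,0.14786,0.059325,0.61695
54,0.38647,0.14753,0.057456,0.59146
55,0.36489,0.14719,0.055674,0.56775
56,0.34484,0.14685,0.053974,0.54567
57,0.32621,0.14651,0.052351,0.52508
58,0.30888,0.14617,0.0508,0.50585
59,0.29272,0.14583,0.049316,0.48787
60,0.27765,0.14549,0.047897,0.47104
61,0.26357,0.14515,0.046538,0.45526
62,0.25041,0.14481,0.045236,0.44046
63,0.2381,0.14447,0.043988,0.42656
64,0.22656,0.14413,0.042791,0.41348
65,0.21573,0.14379,0.041643,0.40117
66,0.20558,0.14346,0.040539,0.38957
67,0.19603,0.14312,0.03948,0.37863
68,0.18706,0.14278,0.038461,0.3683
69,0.17861,0.14245,0.037481,0.35854
70,0.17065,0.14211,0.036538,0.3493
71,0.16315,0.14178,0.03563,0.34056
72,0.15607,0.14144,0.034755,0.33227
73,0.14939,0.14111,0.033912,0.32441
74,0.14307,0.14078,0.0331,0.31695
75,0.1371,0.14045,0.032316,0.30986
76,0.13144,0.14012,0.03156,0.30313
77,0.12609,0.1398,0.03083,0.29672
78,0.12101,0.13947,0.030125,0.29061
79,0.1162,0.13915,0.029444,0.28479
80,0.11164,0.13882,0.028786,0.27925
81,0.1073,0.1385,0.02815,0.27395
82,0.10318,0.13818,0.027534,0.2689
83,0.099264,0.13786,0.026938,0.26407
84,0.095539,0.13755,0.026362,0.25945
85,0.091993,0.13723,0.025803,0.25503
86,0.088616,0.13692,0.025263,0.2508
87,0.085399,0.1366,0.024739,0.24674
88,0.082331,0.13629,0.024231,0.24286
89,0.079405,0.13598,0.023739,0.23913
90,0.076613,0.13568,0.023261,0.23555
91,0.073947,0.13537,0.022798,0.23211
92,0.0714,0.13506,0.022348,0.22881
93,0.068965,0.13476,0.021912,0.22564
94,0.066638,0.13446,0.021488,0.22258
95,0.064411,0.13416,0.021076,0.21964
96,0.062279,0.13386,0.020676,0.21681
97,0.060239,0.13356,0.020288,0.21409
98,0.058284,0.13327,0.01991,0.21146
99,0.056411,0.13297,0.019542,0.20892
100,0.054615,0.13268,0.019185,0.20648
101,0.052892,0.13239,0.018837,0.20412
102,0.051239,0.1321,0.018499,0.20184
103,0.049653,0.13181,0.018169,0.19963
104,0.04813,0.13152,0.017849,0.1975
105,0.046666,0.13124,0.017537,0.19544
106,0.04526,0.13096,0.017232,0.19345
107,0.043908,0.13067,0.016936,0.19152
108,0.042609,0.13039,0.016647,0.18965
109,0.041358,0.13011,0.016366,0.18784
110,0.040155,0.12984,0.016092,0.18608
111,0.038996,0.12956,0.015824,0.18438
112,0.037881,0.12929,0.015563,0.18273
113,0.036807,0.12901,0.015309,0.18113
114,0.035771,0.12874,0.01506,0.17957
115,0.034773,0.12847,0.014818,0.17806
116,0.033811,0.1282,0.014581,0.1766
117,0.032883,0.12794,0.01435,0.17517
118,0.031988,0.12767,0.014125,0.17378
119,0.031124,0.12741,0.013904,0.17244
120,0.03029,0.12714,0.013689,0.17112
121,0.029485,0.12688,0.013479,0.16985
122,0.028707,0.12662,0.013273,0.1686
123,0.027955,0.12637,0.013073,0.16739
124,0.027229,0.12611,0.012876,0.16621
125,0.026527,0.12585,0.012684,0.16506
126,0.025848,0.1256,0.012497,0.16394
127,0.025192,0.12535,0.012313,0.16285
128,0.024557,0.12509,0.012133,0.16178
129,0.023942,0.12484,0.011958,0.16074
130,0.023348,0.1246,0.011786,0.15973
131,0.022772,0.12435,0.011618,0.15874
132,0.022214,0.1241,0.011453,0.15777
133,0.021674,0.12386,0.011292,0.15682
134,0.021151,0.12361,0.011134,0.1559
135,0.020644,0.12337,0.010979,0.15499
136,0.020153,0.12313,0.010828,0.15411
137,0.019676,0.12289,0.01068,0.15325
138,0.019215,0.12265,0.010535,0.1524
139,0.018767,0.12241,0.010392,0.15157
140,0.018332,0.12218,0.010253,0.15076
141,0.01791,0.12194,0.010116,0.14997
142,0.017501,0.12171,0.0099822,0.14919
143,0.017104,0.12148,0.0098509,0.14843
144,0.016718,0.12125,0.0097221,0.14769
145,0.016344,0.12102,0.0095958,0.14696
146,0.01598,0.12079,0.009472,0.14624
147,0.015627,0.12056,0.0093505,0.14554
148,0.015284,0.12034,0.0092314,0.14485
149,0.01495,0.12011,0.0091145,0.14418
150,0.014626,0.11989,0.0089998,0.14351
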