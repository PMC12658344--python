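energy_keV,muen_over_rho
1,3457.4
1.5,1134.5
2,501.78
2.5,263.13
3,154.16
3.5,109.82
4,74.065
4.5,52.207
5,38.111
5.5,28.625
6,22.014
6.5,17.271
7,13.782
7.5,11.161
8,9.1567
8.5,7.5988
9,6.3695
9.5,5.3843
10,4.59
10.5,3.9417
11,3.4086
11.5,2.9663
12,2.5964
12.5,2.2849
13,2.0206
13.5,1.7952
14,1.6016
14.5,1.4345
15,1.2896
15.5,1.1634
16,1.0529
16.5,0.95594
17,0.87039
17.5,0.79468
18,0.72744
18.5,0.66754
19,0.61401
19.5,0.56603
20,0.52291
21,0.44898
22,0.38839
23,0.3383
24,0.29655
25,0.26151
26,0.23189
27,0.20665
28,0.18496
29,0.16633
30,0.15026
31,0.13634
32,0.12421
33,0.11361
34,0.10431
35,0.096121
36,0.088888
37,0.082477
38,0.076781
39,0.071705
40,0.067169
41,0.063108
42,0.059463
43,0.056185
44,0.05323
45,0.050562
46,0.048149
47,0.045964
48,0.04398
49,0.042178
50,0.040538
51,0.039044
52,0.037682
53,0.036438
54,0.035301
55,0.034261
56,0.033309
57,0.032436
58,0.031636
59,0.030902
60,0.030229
61,0.02961
62,0.029042
63,0.028519
64,0.028039
65,0.027598
66,0.027193
67,0.02682
68,0.026477
69,0.026162
70,0.025873
71,0.025607
72,0.025364
73,0.02514
74,0.024935
75,0.024748
76,0.024576
77,0.02442
78,0.024277
79,0.024147
80,0.02403
81,0.023923
82,0.023826
83,0.02374
84,0.023662
85,0.023592
86,0.02353
87,0.023476
88,0.023428
89,0.023386
90,0.023351
91,0.02332
92,0.023295
93,0.023275
94,0.023259
95,0.023248
96,0.02324
97,0.023236
98,0.023235
99,0.023237
100,0.023243
101,0.023251
102,0.023261
103,0.023275
104,0.02329
105,0.023307
106,0.023327
107,0.023348
108,0.023371
109,0.023396
110,0.023422
111,0.023449
112,0.023478
113,0.023507
114,0.023538
115,0.02357
116,0.023603
117,0.023637
118,0.023671
119,0.023707
120,0.023743
121,0.023779
122,0.023817
123,0.023854
124,0.023892
125,0.023931
126,0.02397
127,0.02401
128,0.024049
129,0.024089
130,0.024129
131,0.02417
132,0.024211
133,0.024251
134,0.024292
135,0.024333
136,0.024374
137,0.024416
138,0.024457
139,0.024498
140,0.02454
141,0.024581
142,0.024622
143,0.024663
144,0.024705
145,0.024746
146,0.024787
147,0.024828
148,0.024868
149,0.024909
150,0.02495
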