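energy_keV,fluence
1.25,0
1.75,0
2.25,0
2.75,0
3.25,0
3.75,0
4.25,0
4.75,0
5.25,0
5.75,0
6.25,0
6.75,0
7.25,0
7.75,0
8.25,0
8.75,5.00640431745e-11
9.25,2.41119815599e-09
9.75,5.57175373806e-08
10.25,3.21289956611e-07
10.75,2.95587733793e-06
11.25,1.84740534623e-05
11.75,6.08527178533e-05
12.25,0.000192421098844
12.75,0.000594478748491
13.25,0.00155744000243
13.75,0.00356003814605
14.25,0.00725908828305
14.75,0.0134511761513
15.25,0.0229953322863
15.75,0.0367169469011
16.25,0.0553069224409
16.75,0.079256547892
17.25,0.108804397209
17.75,0.143935240685
18.25,0.184391864771
18.75,0.229712818723
19.25,0.279265086843
19.75,0.332318128994
20.25,0.388080625651
20.75,0.445748776557
21.25,0.504540306779
21.75,0.563717643089
22.25,0.622575627269
22.75,0.680516593035
23.25,0.737042716012
23.75,0.791723000846
24.25,0.844188541678
24.75,0.894164398415
25.25,0.941454388956
25.75,0.985913377915
26.25,1.02743573329
26.75,1.06597833204
27.25,1.101552431
27.75,1.13418448517
28.25,1.16390862782
28.75,1.1908013348
29.25,1.21493876446
29.75,1.23642789855
30.25,1.25538648008
30.75,1.27193557005
31.25,1.2861981104
31.75,1.29830025258
32.25,1.30836336411
32.75,1.31651152285
33.25,1.32287004491
33.75,1.32755670956
34.25,1.33067853089
34.75,1.33234495747
35.25,1.33266179409
35.75,1.33172839087
36.25,1.32964199751
36.75,1.32649159042
37.25,1.32235382928
37.75,1.3173085067
38.25,1.31143302822
38.75,1.30479730425
39.25,1.29746322138
39.75,1.28949221116
40.25,1.28094629577
40.75,1.27187870665
41.25,1.26233504659
41.75,1.25236157432
42.25,1.24200064302
42.75,1.2312922552
43.25,1.22027553744
43.75,1.2089850414
44.25,1.19745197685
44.75,1.18570546762
45.25,1.17377166785
45.75,1.16167599558
46.25,1.14944248808
46.75,1.13709273782
47.25,1.12464351196
47.75,1.11211325633
48.25,1.09952135014
48.75,1.08688343069
49.25,1.07421321785
49.75,1.06152384623
50.25,1.04882811864
50.75,1.03613715266
51.25,1.02345932052
51.75,1.01080388097
52.25,0.998182058159
52.75,0.985601495738
53.25,0.973065927424
53.75,0.960581860973
54.25,0.948155630311
54.75,0.935792791798
55.25,0.923499415472
55.75,0.911279646225
56.25,0.899135593756
56.75,0.887071062765
57.25,0.875092015822
57.75,1.40739837989
58.25,0.85139826343
58.75,0.83968600494
59.25,1.77337993212
59.75,0.816537945162
60.25,0.80510771367
60.75,0.793775818297
61.25,0.782540930716
61.75,0.771403989651
62.25,0.760368250047
62.75,0.749434174923
63.25,0.738599641367
63.75,0.727864983491
64.25,0.717231502889
64.75,0.706699242551
65.25,0.696269355829
65.75,0.685941611488
66.25,0.675713411445
66.75,0.665584506033
67.25,0.978253153713
67.75,0.645626447961
68.25,0.635795147943
68.75,0.626061276262
69.25,0.704952985378
69.75,0.579309389316
70.25,0.570752526845
70.75,0.562264619414
71.25,0.553845150183
71.75,0.545494129933
72.25,0.537212528455
72.75,0.529000198932
73.25,0.520862549443
73.75,0.512798798611
74.25,0.504800098
74.75,0.496866465923
75.25,0.488997663906
75.75,0.48119364153
76.25,0.473456098012
76.75,0.465784785888
77.25,0.458177777934
77.75,0.450634872242
78.25,0.443157390491
78.75,0.435744970621
79.25,0.42839576013
79.75,0.42110945179
80.25,0.413885775157
80.75,0.406724401369
81.25,0.399625703774
81.75,0.392589236809
82.25,0.385613809769
82.75,0.378699003075
83.25,0.371845677667
83.75,0.365053302365
84.25,0.358320128157
84.75,0.351645694586
85.25,0.345030063894
85.75,0.338472724973
86.25,0.331973144466
86.75,0.325530805308
87.25,0.319145305813
87.75,0.312816108009
88.25,0.306542587537
88.75,0.300324213252
89.25,0.294159956265
89.75,0.288049321702
90.25,0.281992625453
90.75,0.275989294165
91.25,0.270038650675
91.75,0.264140142098
92.25,0.258292946086
92.75,0.252496546763
93.25,0.246750422743
93.75,0.241054062004
94.25,0.235406665312
94.75,0.229807744482
95.25,0.224257544121
95.75,0.218755519272
96.25,0.213300325429
96.75,0.207891499633
97.25,0.202528979608
97.75,0.19721226859
98.25,0.191940850424
98.75,0.18671423933
99.25,0.181531672176
99.75,0.17639269615
100.25,0.171297369422
100.75,0.166245198524
101.25,0.161235230256
101.75,0.156267025742
102.25,0.151340393677
102.75,0.146454876643
103.25,0.141609954277
103.75,0.136805188743
104.25,0.132040235476
104.75,0.127314650819
105.25,0.122627930564
105.75,0.117979651784
106.25,0.113369224221
106.75,0.108796255195
107.25,0.104260541131
107.75,0.09976167058
108.25,0.0952992035106
108.75,0.0908727439864
109.25,0.0864819383779
109.75,0.0821263920848
110.25,0.0778056906286
110.75,0.0735194536468
111.25,0.0692673086774
111.75,0.0650488833968
112.25,0.0608637142126
112.75,0.056711457452
113.25,0.0525918575166
113.75,0.0485045582029
114.25,0.0444492019824
114.75,0.0404254427691
115.25,0.0364329448912
115.75,0.0324713680786
116.25,0.0285403760166
116.75,0.0246396369349
117.25,0.0207688207546
117.75,0.016927605264
118.25,0.0131156505933
118.75,0.00933266110167
119.25,0.00557835330995
119.75,0.00185242055036
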