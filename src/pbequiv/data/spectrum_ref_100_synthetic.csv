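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
8.75,4.10637657499e-11
9.25,1.97576733775e-09
9.75,4.56100476063e-08
10.25,2.62740533994e-07
10.75,2.41475562847e-06
11.25,1.50765263888e-05
11.75,4.96097214831e-05
12.25,0.000156704885602
12.75,0.000483620240614
13.25,0.00126564796451
13.75,0.00288991331856
14.25,0.0058862110664
14.75,0.0108951331772
15.25,0.018604815382
15.75,0.0296729283109
16.25,0.0446453470306
16.75,0.0639041899468
17.25,0.087625925733
17.75,0.115781648375
18.25,0.148147763587
18.75,0.184337447124
19.25,0.22382784876
19.75,0.266020247898
20.25,0.310269973891
20.75,0.355925345513
21.25,0.402354928191
21.75,0.448965960017
22.25,0.495194424759
22.75,0.540564594467
23.25,0.58468246464
23.75,0.62720913054
24.25,0.667856731406
24.75,0.706413343629
25.25,0.742730507382
25.75,0.776700990029
26.25,0.808249443519
26.75,0.837350271552
27.25,0.864020909489
27.75,0.888290829846
28.25,0.910195575434
28.75,0.929803781966
29.25,0.947183664852
29.75,0.962427256215
30.25,0.975634618226
30.75,0.986907991329
31.25,0.996350648903
31.75,1.00406790072
32.25,1.01016088796
32.75,1.01473237721
33.25,1.01788559652
33.75,1.01971747256
34.25,1.02031619132
34.75,1.01977136041
35.25,1.01816933531
35.75,1.0155910874
36.25,1.01211555034
36.75,1.00781493206
37.25,1.00275169531
37.75,0.996990328776
38.25,0.990593143637
38.75,0.983616429361
39.25,0.976110101536
39.75,0.96812343579
40.25,0.959705845423
40.75,0.950899853235
41.25,0.941742018881
41.75,0.932269159159
42.25,0.922514947066
42.75,0.912511088806
43.25,0.902288426705
43.75,0.891874210866
44.25,0.881293039069
44.75,0.870567801805
45.25,0.859719047686
45.75,0.848766636503
46.25,0.837729270976
46.75,0.826623730909
47.25,0.815463165027
47.75,0.804261835892
48.25,0.793034562643
48.75,0.781793344883
49.25,0.770548703969
49.75,0.759310651571
50.25,0.748088873149
50.75,0.736891765612
51.25,0.725725700004
51.75,0.714597615485
52.25,0.703515767928
52.75,0.692485809273
53.25,0.681510593364
53.75,0.670594884076
54.25,0.659743271281
54.75,0.648959752167
55.25,0.63824863077
55.75,0.62761283028
56.25,0.617053838852
56.75,0.606574284025
57.25,0.596178225918
57.75,0.772144869671
58.25,0.575641740861
58.75,0.565502819653
59.25,0.879030244353
59.75,0.545488004859
60.25,0.53561559194
60.75,0.525834613809
61.25,0.516144018132
61.75,0.506544250715
62.25,0.49703725436
62.75,0.487623109448
63.25,0.478300208286
63.75,0.469068544917
64.25,0.459928721583
64.75,0.450880512216
65.25,0.441924385663
65.75,0.4330599114
66.25,0.424285165326
66.75,0.415599715035
67.25,0.517462366407
67.75,0.398496707114
68.25,0.390077216371
68.75,0.381744680648
69.25,0.403802113416
69.75,0.348738488096
70.25,0.341304274847
70.75,0.333933809499
71.25,0.326626627031
71.75,0.319382573484
72.25,0.312202045333
72.75,0.305084770813
73.25,0.298033651286
73.75,0.291047966779
74.25,0.28412245953
74.75,0.277256978222
75.25,0.270451221937
75.75,0.263704989991
76.25,0.257019024635
76.75,0.250392977385
77.25,0.243825601123
77.75,0.237316589524
78.25,0.230866424986
78.75,0.224474681835
79.25,0.218140172336
79.75,0.211862519224
80.25,0.205641359983
80.75,0.199476298761
81.25,0.19336727602
81.75,0.18731381887
82.25,0.181315102607
82.75,0.175370679276
83.25,0.169480683018
83.75,0.163644583819
84.25,0.157861315202
84.75,0.152130406878
85.25,0.146451609854
85.75,0.140824418419
86.25,0.135248318116
86.75,0.129722802115
87.25,0.124247409133
87.75,0.118821622422
88.25,0.1134448946
88.75,0.108116716771
89.25,0.102836407475
89.75,0.0976034891717
90.25,0.0924177511988
90.75,0.0872786656763
91.25,0.0821856762922
91.75,0.0771382715861
92.25,0.0721358678259
92.75,0.0671779803315
93.25,0.0622641253651
93.75,0.0573938242868
94.25,0.0525665369143
94.75,0.0477818082587
95.25,0.0430393266495
95.75,0.0383385961611
96.25,0.033678998752
96.75,0.0290601020992
97.25,0.0244815250076
97.75,0.0199428136776
98.25,0.0154435167008
98.75,0.0109831905488
99.25,0.0065613857413
99.75,0.00217768760679
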