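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
8.75,3.20634883252e-11
9.25,1.54033651952e-09
9.75,3.55025578321e-08
10.25,2.04191111377e-07
10.75,1.87363391901e-06
11.25,1.16789993153e-05
11.75,3.8366725113e-05
12.25,0.000120988672359
12.75,0.000372761732737
13.25,0.000973855926579
13.75,0.00221978849107
14.25,0.00451333384974
14.75,0.00833909020305
15.25,0.0142142984777
15.75,0.0226289097208
16.25,0.0339837716203
16.75,0.0485518320016
17.25,0.0664474542568
17.75,0.087628056065
18.25,0.111903662404
18.75,0.138962075524
19.25,0.168390610677
19.75,0.199722366802
20.25,0.232459322132
20.75,0.266101914469
21.25,0.300169549603
21.75,0.334214276946
22.25,0.367813222249
22.75,0.4006125959
23.25,0.432322213268
23.75,0.462695260235
24.25,0.491524921134
24.75,0.518662288844
25.25,0.544006625808
25.75,0.567488602142
26.25,0.589063153751
26.75,0.60872221106
27.25,0.62648938798
27.75,0.642397174526
28.25,0.656482523048
28.75,0.668806229133
29.25,0.679428565247
29.75,0.688426613876
30.25,0.695882756369
30.75,0.701880412606
31.25,0.706503187404
31.75,0.709835548862
32.25,0.711958411809
32.75,0.712953231572
33.25,0.712901148122
33.75,0.711878235562
34.25,0.709953851757
34.75,0.70719776335
35.25,0.703676876528
35.75,0.69945378393
36.25,0.694589103177
36.75,0.689138273704
37.25,0.683149561348
37.75,0.676672150856
38.25,0.669753259058
38.75,0.662435554468
39.25,0.654756981689
39.75,0.646754660424
40.25,0.638465395072
40.75,0.629920999822
41.25,0.621148991177
41.75,0.612176743997
42.25,0.603029251112
42.75,0.593729922411
43.25,0.584301315972
43.75,0.574763380336
44.25,0.565134101286
44.75,0.555430135993
45.25,0.545666427527
45.75,0.535857277424
46.25,0.526016053869
46.75,0.516154723995
47.25,0.506282818098
47.75,0.496410415455
48.25,0.486547775148
48.75,0.476703259075
49.25,0.466884190089
49.75,0.457097456916
50.25,0.447349627662
50.75,0.437646378561
51.25,0.42799207949
51.75,0.418391349999
52.25,0.408849477696
52.75,0.399370122808
53.25,0.389955259305
53.75,0.380607907178
54.25,0.371330912251
54.75,0.362126712535
55.25,0.352997846068
55.75,0.343946014334
56.25,0.334972083948
56.75,0.326077505285
57.25,0.317264436015
57.75,0.330999555074
58.25,0.299885218293
58.75,0.291319634367
59.25,0.321862121622
59.75,0.274438064556
60.25,0.266123470209
60.75,0.25789340932
61.25,0.249747105548
61.75,0.241684511779
62.25,0.233706258672
62.75,0.225812043973
63.25,0.218000775205
63.75,0.210272106342
64.25,0.202625940278
64.75,0.195061781881
65.25,0.187579415497
65.75,0.180178211312
66.25,0.172856919207
66.75,0.165614924036
67.25,0.171773619944
67.75,0.151366966268
68.25,0.144359284799
68.75,0.137428085033
69.25,0.134227635384
69.75,0.118167586875
70.25,0.111856022849
70.75,0.105602999585
71.25,0.0994081038789
71.75,0.0932710170352
72.25,0.08719156221
72.75,0.0811693426933
73.25,0.0752047531282
73.75,0.0692971349474
74.25,0.0634448210601
74.75,0.0576474905214
75.25,0.0519047799676
75.75,0.046216338452
76.25,0.0405819512581
76.75,0.0350011688817
77.25,0.0294734243116
77.75,0.0239983068058
78.25,0.0185754594816
78.75,0.0132043930491
79.25,0.00788458454227
79.75,0.00261558665708
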