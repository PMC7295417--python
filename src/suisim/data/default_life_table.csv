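age,qx
40,0.0008589685195752603
41,0.0009436282386154492
42,0.0010366319980536578
43,0.0011388021843914385
44,0.0012510422383349815
45,0.0013743446434769302
46,0.001509799702340644
47,0.001658605177389163
48,0.0018220768822495483
49,0.002001660316805619
50,0.002198943449042471
51,0.002415670756666329
52,0.0026537586526629094
53,0.002915312431194868
54,0.0032026448836826107
55,0.003518296749681306
56,0.003865059183391115
57,0.00424599843446098
58,0.004664482961326173
59,0.005124213216829468
60,0.005629254369505602
61,0.006184072249867214
62,0.006793572839547575
63,0.007463145652483192
64,0.008198711391734798
65,0.00900677430335242
66,0.009894479690224159
67,0.01086967709447529
68,0.011940989707108503
69,0.013117890618640696
70,0.014410786584983204
71,0.015831110049265767
72,0.017391420233308207
73,0.019105514192641865
74,0.02098854881708561
75,0.02305717485566775
76,0.02532968415101022
77,0.02782617138509606
78,0.030568711766658842
79,0.03358155623139607
80,0.03689134588106572
81,0.04052734755764614
82,0.04452171263562476
83,0.04890976132078932
84,0.053730294969435946
85,0.05902593918967837
86,0.06484352075873558
87,0.07123448168909162
88,0.07825533410491001
89,0.08596815995095344
90,0.09444115995268647
91,0.10374925668174637
92,0.11397475705939485
93,0.12520808015614057
94,0.1375485567231068
95,0.15110530752501009
96,0.16599820824141168
97,0.1823589494683912
98,0.20033220119371845
99,0.22007689204239936
100,1.0
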