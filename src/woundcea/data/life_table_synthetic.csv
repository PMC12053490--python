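# Synthetic life table (Gompertz-generated) -- NOT real national statistics.
# Annual death probability q(age) = 1 - exp(-a*exp(b*age)) with a=3.0e-5, b=0.092,
# chosen to resemble recent UK unisex rates (q(63) ~ 0.010); q capped at 1 at age 100.
age,qx
18,0.000157137
19,0.000172278
20,0.000188878
21,0.000207078
22,0.00022703
23,0.000248905
24,0.000272888
25,0.000299181
26,0.000328006
27,0.000359609
28,0.000394256
29,0.00043224
30,0.000473883
31,0.000519537
32,0.000569588
33,0.000624459
34,0.000684614
35,0.000750562
36,0.00082286
37,0.000902119
38,0.000989008
39,0.00108426
40,0.00118868
41,0.00130316
42,0.00142865
43,0.00156621
44,0.00171701
45,0.00188231
46,0.00206351
47,0.00226214
48,0.00247986
49,0.0027185
50,0.00298008
51,0.00326679
52,0.00358102
53,0.00392543
54,0.00430289
55,0.00471656
56,0.00516989
57,0.00566667
58,0.00621104
59,0.00680753
60,0.00746108
61,0.00817712
62,0.00896156
63,0.00982089
64,0.0107622
65,0.0117931
66,0.0129222
67,0.0141586
68,0.0155123
69,0.0169944
70,0.0186167
71,0.0203923
72,0.0223353
73,0.0244611
74,0.0267865
75,0.0293295
76,0.03211
77,0.0351493
78,0.0384705
79,0.0420986
80,0.0460606
81,0.0503855
82,0.0551047
83,0.0602517
84,0.0658625
85,0.0719755
86,0.0786316
87,0.0858743
88,0.0937495
89,0.102306
90,0.111593
91,0.121666
92,0.132578
93,0.144386
94,0.157147
95,0.170919
96,0.185759
97,0.201725
98,0.21887
99,0.237244
100,1
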