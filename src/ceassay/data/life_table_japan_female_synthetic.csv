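age,q_annual
0,0.00020652
1,0.00020725
2,0.00020805
3,0.00020895
4,0.00020994
5,0.00021104
6,0.00021227
7,0.00021363
8,0.00021514
9,0.00021682
10,0.00021868
11,0.00022075
12,0.00022305
13,0.00022561
14,0.00022844
15,0.00023159
16,0.00023509
17,0.00023898
18,0.0002433
19,0.0002481
20,0.00025342
21,0.00025934
22,0.00026591
23,0.00027321
24,0.00028132
25,0.00029032
26,0.00030032
27,0.00031143
28,0.00032377
29,0.00033747
30,0.00035269
31,0.0003696
32,0.00038837
33,0.00040923
34,0.00043239
35,0.00045812
36,0.00048669
37,0.00051843
38,0.00055368
39,0.00059283
40,0.00063631
41,0.00068461
42,0.00073825
43,0.00079782
44,0.00086399
45,0.00093747
46,0.00101908
47,0.00110973
48,0.00121039
49,0.0013222
50,0.00144636
51,0.00158425
52,0.00173739
53,0.00190745
54,0.0020963
55,0.00230603
56,0.00253892
57,0.00279752
58,0.00308468
59,0.00340354
60,0.00375758
61,0.00415066
62,0.00458708
63,0.00507159
64,0.00560947
65,0.00620656
66,0.00686933
67,0.00760495
68,0.00842138
69,0.00932741
70,0.01033278
71,0.01144826
72,0.01268575
73,0.01405844
74,0.01558086
75,0.01726907
76,0.01914079
77,0.02121555
78,0.02351486
79,0.02606241
80,0.0288842
81,0.03200881
82,0.03546757
83,0.03929477
84,0.04352787
85,0.04820777
86,0.05337894
87,0.05908969
88,0.06539231
89,0.07234322
90,0.08000309
91,0.08843687
92,0.09771376
93,0.10790707
94,0.11909397
95,0.13135501
96,0.14477353
97,0.15943479
98,0.17542478
99,0.19282872
100,0.21172921
101,0.23220386
102,0.25432249
103,0.27814377
104,0.30371135
105,0.33104941
106,0.36015773
107,0.39100636
108,0.42352999
109,0.45762236
110,0.49313094
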