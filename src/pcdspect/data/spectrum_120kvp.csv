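# 120 kVp tungsten, 3.0 mm Al-equivalent total filtration; relative fluence per 1 keV bin
energy_keV,photons_per_bin
15,1.65088062e-04
16,4.62349129e-04
17,1.02256170e-03
18,1.89933770e-03
19,3.09397155e-03
20,4.55961106e-03
21,6.10017044e-03
22,7.72354207e-03
23,9.35848633e-03
24,1.09454590e-02
25,1.24391895e-02
26,1.38084890e-02
27,1.50345295e-02
28,1.61084992e-02
29,1.70291988e-02
30,1.78008783e-02
31,1.82451839e-02
32,1.85853696e-02
33,1.88313614e-02
34,1.89929124e-02
35,1.90793547e-02
36,1.90994464e-02
37,1.90612885e-02
38,1.89722911e-02
39,1.88391726e-02
40,1.86679816e-02
41,1.83779992e-02
42,1.80732607e-02
43,1.77565015e-02
44,1.74301158e-02
45,1.70961950e-02
46,1.67565634e-02
47,1.64128089e-02
48,1.60663113e-02
49,1.57182671e-02
50,1.53697114e-02
51,1.49869657e-02
52,1.46099206e-02
53,1.42387441e-02
54,1.38735604e-02
55,1.35144560e-02
56,1.31614849e-02
57,1.28146737e-02
58,3.84329638e-02
59,5.72071241e-02
60,1.18111317e-02
61,1.14707368e-02
62,1.11383946e-02
63,1.08138482e-02
64,1.04968498e-02
65,1.01871606e-02
66,9.88455013e-03
67,2.48216455e-02
68,9.29968477e-03
69,1.27576205e-02
70,8.74057181e-03
71,8.47018002e-03
72,8.20564968e-03
73,7.94680306e-03
74,7.69346889e-03
75,7.44548216e-03
76,7.20268387e-03
77,6.96492079e-03
78,6.73204524e-03
79,6.50391487e-03
80,6.28039246e-03
81,6.05705306e-03
82,5.83851322e-03
83,5.62461869e-03
84,5.41522181e-03
85,5.21018111e-03
86,5.00936104e-03
87,4.81263159e-03
88,4.61986808e-03
89,4.43095087e-03
90,4.24576507e-03
91,4.06420037e-03
92,3.88615074e-03
93,3.71151430e-03
94,3.54019307e-03
95,3.37209279e-03
96,3.20712277e-03
97,3.04519567e-03
98,2.88622742e-03
99,2.73013702e-03
100,2.57684639e-03
101,2.42550515e-03
102,2.27692687e-03
103,2.13103545e-03
104,1.98775754e-03
105,1.84702249e-03
106,1.70876218e-03
107,1.57291093e-03
108,1.43940537e-03
109,1.30818434e-03
110,1.17918884e-03
111,1.05236187e-03
112,9.27648376e-04
113,8.04995181e-04
114,6.84350879e-04
115,5.65665779e-04
116,4.48891823e-04
117,3.33982529e-04
118,2.20892916e-04
119,1.09579455e-04
120,0.00000000e+00
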