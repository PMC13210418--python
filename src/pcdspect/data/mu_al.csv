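# linear attenuation of Al, density 2.699 g/cm^3
energy_keV,mu_per_mm
15,2.147055e+00
16,1.779071e+00
17,1.491061e+00
18,1.262358e+00
19,1.078401e+00
20,9.287259e-01
21,8.120859e-01
22,7.145430e-01
23,6.323034e-01
24,5.624489e-01
25,5.027087e-01
26,4.512973e-01
27,4.067967e-01
28,3.680714e-01
29,3.342038e-01
30,3.044472e-01
31,2.815750e-01
32,2.610678e-01
33,2.426180e-01
34,2.259660e-01
35,2.108912e-01
36,1.972052e-01
37,1.847468e-01
38,1.733769e-01
39,1.629754e-01
40,1.534381e-01
41,1.462329e-01
42,1.395276e-01
43,1.332769e-01
44,1.274404e-01
45,1.219823e-01
46,1.168703e-01
47,1.120756e-01
48,1.075725e-01
49,1.033377e-01
50,9.935019e-02
51,9.635904e-02
52,9.351344e-02
53,9.080370e-02
54,8.822097e-02
55,8.575709e-02
56,8.340458e-02
57,8.115656e-02
58,7.900666e-02
59,7.694902e-02
60,7.497822e-02
61,7.361384e-02
62,7.229588e-02
63,7.102204e-02
64,6.979017e-02
65,6.859829e-02
66,6.744449e-02
67,6.632702e-02
68,6.524421e-02
69,6.419450e-02
70,6.317642e-02
71,6.218859e-02
72,6.122970e-02
73,6.029852e-02
74,5.939388e-02
75,5.851469e-02
76,5.765990e-02
77,5.682852e-02
78,5.601964e-02
79,5.523235e-02
80,5.446582e-02
81,5.395541e-02
82,5.345595e-02
83,5.296709e-02
84,5.248847e-02
85,5.201977e-02
86,5.156066e-02
87,5.111084e-02
88,5.067002e-02
89,5.023791e-02
90,4.981426e-02
91,4.939881e-02
92,4.899130e-02
93,4.859151e-02
94,4.819920e-02
95,4.781416e-02
96,4.743618e-02
97,4.706506e-02
98,4.670061e-02
99,4.634263e-02
100,4.599096e-02
101,4.575192e-02
102,4.551646e-02
103,4.528449e-02
104,4.505593e-02
105,4.483070e-02
106,4.460870e-02
107,4.438988e-02
108,4.417415e-02
109,4.396144e-02
110,4.375169e-02
111,4.354482e-02
112,4.334077e-02
113,4.313948e-02
114,4.294088e-02
115,4.274492e-02
116,4.255154e-02
117,4.236069e-02
118,4.217230e-02
119,4.198633e-02
120,4.180273e-02
121,4.162144e-02
122,4.144242e-02
123,4.126563e-02
124,4.109101e-02
125,4.091852e-02
126,4.074813e-02
127,4.057978e-02
128,4.041344e-02
129,4.024906e-02
130,4.008662e-02
131,3.992607e-02
132,3.976738e-02
133,3.961051e-02
134,3.945542e-02
135,3.930209e-02
136,3.915048e-02
137,3.900056e-02
138,3.885230e-02
139,3.870566e-02
140,3.856063e-02
141,3.841716e-02
142,3.827524e-02
143,3.813483e-02
144,3.799591e-02
145,3.785845e-02
146,3.772242e-02
147,3.758781e-02
148,3.745459e-02
149,3.732274e-02
150,3.719222e-02
151,3.708986e-02
152,3.698845e-02
153,3.688798e-02
154,3.678844e-02
155,3.668980e-02
156,3.659207e-02
157,3.649521e-02
158,3.639922e-02
159,3.630409e-02
160,3.620981e-02
161,3.611635e-02
162,3.602371e-02
163,3.593187e-02
164,3.584083e-02
165,3.575057e-02
166,3.566109e-02
167,3.557236e-02
168,3.548438e-02
169,3.539713e-02
170,3.531062e-02
171,3.522482e-02
172,3.513973e-02
173,3.505534e-02
174,3.497163e-02
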