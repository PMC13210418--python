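# linear attenuation of CdTe, density 5.85 g/cm^3
energy_keV,mu_per_mm
15,2.586932e+01
16,2.165589e+01
17,1.831756e+01
18,1.563844e+01
19,1.346313e+01
20,1.167798e+01
21,1.019889e+01
22,8.962922e+00
23,7.922010e+00
24,7.039068e+00
25,6.285024e+00
26,5.637027e+00
27,1.642425e+01
28,1.487284e+01
29,1.355376e+01
30,1.238919e+01
31,1.135616e+01
32,1.985966e+01
33,1.831677e+01
34,1.693401e+01
35,1.568912e+01
36,1.456353e+01
37,1.354437e+01
38,1.261926e+01
39,1.177749e+01
40,1.100982e+01
41,1.030819e+01
42,9.665255e+00
43,9.075148e+00
44,8.532700e+00
45,8.033162e+00
46,7.572344e+00
47,7.146541e+00
48,6.752469e+00
49,6.387209e+00
50,6.048158e+00
51,5.732994e+00
52,5.439639e+00
53,5.166228e+00
54,4.910786e+00
55,4.671969e+00
56,4.448645e+00
57,4.239571e+00
58,4.043621e+00
59,3.859778e+00
60,3.687115e+00
61,3.524790e+00
62,3.372039e+00
63,3.228161e+00
64,3.092435e+00
65,2.964255e+00
66,2.843240e+00
67,2.728893e+00
68,2.620758e+00
69,2.518417e+00
70,2.421485e+00
71,2.329608e+00
72,2.242458e+00
73,2.159733e+00
74,2.081156e+00
75,2.006467e+00
76,1.935428e+00
77,1.867817e+00
78,1.803430e+00
79,1.742075e+00
80,1.683575e+00
81,1.627128e+00
82,1.573302e+00
83,1.521944e+00
84,1.472913e+00
85,1.426078e+00
86,1.381317e+00
87,1.338515e+00
88,1.297564e+00
89,1.258365e+00
90,1.220825e+00
91,1.184856e+00
92,1.150375e+00
93,1.117306e+00
94,1.085577e+00
95,1.055120e+00
96,1.025870e+00
97,9.977694e-01
98,9.707602e-01
99,9.447897e-01
100,9.198082e-01
101,8.957683e-01
102,8.726258e-01
103,8.503387e-01
104,8.288675e-01
105,8.081747e-01
106,7.882249e-01
107,7.689849e-01
108,7.504228e-01
109,7.325089e-01
110,7.152147e-01
111,6.985134e-01
112,6.823794e-01
113,6.667887e-01
114,6.517181e-01
115,6.371461e-01
116,6.230518e-01
117,6.094156e-01
118,5.962188e-01
119,5.834436e-01
120,5.710732e-01
121,5.590913e-01
122,5.474827e-01
123,5.362327e-01
124,5.253273e-01
125,5.147534e-01
126,5.044983e-01
127,4.945497e-01
128,4.848963e-01
129,4.755270e-01
130,4.664312e-01
131,4.575989e-01
132,4.490204e-01
133,4.406866e-01
134,4.325888e-01
135,4.247183e-01
136,4.170673e-01
137,4.096279e-01
138,4.023928e-01
139,3.953549e-01
140,3.885075e-01
141,3.818439e-01
142,3.753580e-01
143,3.690438e-01
144,3.628956e-01
145,3.569077e-01
146,3.510750e-01
147,3.453923e-01
148,3.398547e-01
149,3.344576e-01
150,3.291965e-01
151,3.240670e-01
152,3.190649e-01
153,3.141862e-01
154,3.094271e-01
155,3.047838e-01
156,3.002528e-01
157,2.958306e-01
158,2.915139e-01
159,2.872996e-01
160,2.831844e-01
161,2.791655e-01
162,2.752400e-01
163,2.714051e-01
164,2.676582e-01
165,2.639967e-01
166,2.604181e-01
167,2.569201e-01
168,2.535003e-01
169,2.501564e-01
170,2.468864e-01
171,2.436882e-01
172,2.405598e-01
173,2.374991e-01
174,2.345044e-01
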