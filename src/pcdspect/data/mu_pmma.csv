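# linear attenuation of PMMA, density 1.18 g/cm^3
energy_keV,mu_per_mm
15,1.299180e-01
16,1.121416e-01
17,9.766515e-02
18,8.573230e-02
19,7.578968e-02
20,6.742520e-02
21,6.247492e-02
22,5.809384e-02
23,5.419488e-02
24,5.070733e-02
25,4.757323e-02
26,4.474469e-02
27,4.218180e-02
28,3.985111e-02
29,3.772437e-02
30,3.577760e-02
31,3.475346e-02
32,3.378979e-02
33,3.288128e-02
34,3.202324e-02
35,3.121151e-02
36,3.044237e-02
37,2.971249e-02
38,2.901888e-02
39,2.835886e-02
40,2.773000e-02
41,2.734927e-02
42,2.698275e-02
43,2.662959e-02
44,2.628902e-02
45,2.596032e-02
46,2.564281e-02
47,2.533590e-02
48,2.503900e-02
49,2.475160e-02
50,2.447320e-02
51,2.427446e-02
52,2.408114e-02
53,2.389301e-02
54,2.370982e-02
55,2.353135e-02
56,2.335741e-02
57,2.318780e-02
58,2.302234e-02
59,2.286086e-02
60,2.270320e-02
61,2.258063e-02
62,2.246069e-02
63,2.234330e-02
64,2.222836e-02
65,2.211577e-02
66,2.200546e-02
67,2.189735e-02
68,2.179136e-02
69,2.168742e-02
70,2.158545e-02
71,2.148541e-02
72,2.138722e-02
73,2.129082e-02
74,2.119616e-02
75,2.110318e-02
76,2.101183e-02
77,2.092207e-02
78,2.083384e-02
79,2.074710e-02
80,2.066180e-02
81,2.058730e-02
82,2.051399e-02
83,2.044181e-02
84,2.037076e-02
85,2.030078e-02
86,2.023186e-02
87,2.016397e-02
88,2.009707e-02
89,2.003115e-02
90,1.996618e-02
91,1.990214e-02
92,1.983899e-02
93,1.977673e-02
94,1.971532e-02
95,1.965476e-02
96,1.959501e-02
97,1.953605e-02
98,1.947788e-02
99,1.942047e-02
100,1.936380e-02
101,1.930704e-02
102,1.925101e-02
103,1.919568e-02
104,1.914105e-02
105,1.908709e-02
106,1.903379e-02
107,1.898114e-02
108,1.892912e-02
109,1.887773e-02
110,1.882694e-02
111,1.877674e-02
112,1.872713e-02
113,1.867809e-02
114,1.862960e-02
115,1.858167e-02
116,1.853427e-02
117,1.848739e-02
118,1.844103e-02
119,1.839518e-02
120,1.834983e-02
121,1.830496e-02
122,1.826057e-02
123,1.821665e-02
124,1.817318e-02
125,1.813017e-02
126,1.808761e-02
127,1.804548e-02
128,1.800377e-02
129,1.796249e-02
130,1.792161e-02
131,1.788115e-02
132,1.784108e-02
133,1.780140e-02
134,1.776211e-02
135,1.772319e-02
136,1.768465e-02
137,1.764647e-02
138,1.760865e-02
139,1.757118e-02
140,1.753406e-02
141,1.749729e-02
142,1.746085e-02
143,1.742474e-02
144,1.738895e-02
145,1.735349e-02
146,1.731834e-02
147,1.728350e-02
148,1.724897e-02
149,1.721474e-02
150,1.718080e-02
151,1.714432e-02
152,1.710816e-02
153,1.707232e-02
154,1.703678e-02
155,1.700155e-02
156,1.696661e-02
157,1.693197e-02
158,1.689761e-02
159,1.686355e-02
160,1.682976e-02
161,1.679626e-02
162,1.676302e-02
163,1.673006e-02
164,1.669736e-02
165,1.666493e-02
166,1.663275e-02
167,1.660083e-02
168,1.656915e-02
169,1.653773e-02
170,1.650655e-02
171,1.647561e-02
172,1.644491e-02
173,1.641445e-02
174,1.638422e-02
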