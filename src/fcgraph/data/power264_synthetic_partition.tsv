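node_id	x	y	z	system
0	-25	-98	-12	Sensory/somatomotor Hand
1	27	-97	-13	Sensory/somatomotor Hand
2	24	32	-18	Sensory/somatomotor Hand
3	-56	-45	-24	Sensory/somatomotor Hand
4	8	41	-24	Sensory/somatomotor Hand
5	-21	-22	-20	Sensory/somatomotor Hand
6	17	-28	-17	Sensory/somatomotor Hand
7	-37	-29	-26	Sensory/somatomotor Hand
8	65	-24	-19	Sensory/somatomotor Hand
9	52	-34	-27	Sensory/somatomotor Hand
10	55	-31	-17	Sensory/somatomotor Hand
11	34	38	-12	Sensory/somatomotor Hand
12	-7	-52	61	Sensory/somatomotor Hand
13	-14	-18	40	Sensory/somatomotor Hand
14	0	-15	47	Sensory/somatomotor Hand
15	10	-2	45	Sensory/somatomotor Hand
16	-7	-21	65	Sensory/somatomotor Hand
17	-7	-33	72	Sensory/somatomotor Hand
18	13	-33	75	Sensory/somatomotor Hand
19	-54	-23	43	Sensory/somatomotor Hand
20	29	-17	71	Sensory/somatomotor Hand
21	10	-46	73	Sensory/somatomotor Hand
22	-23	-30	72	Sensory/somatomotor Hand
23	-40	-19	54	Sensory/somatomotor Hand
24	29	-39	59	Sensory/somatomotor Hand
25	50	-20	42	Sensory/somatomotor Hand
26	-38	-27	69	Sensory/somatomotor Hand
27	20	-29	60	Sensory/somatomotor Hand
28	44	-8	57	Sensory/somatomotor Hand
29	-29	-43	61	Sensory/somatomotor Hand
30	10	-17	74	Sensory/somatomotor Mouth
31	22	-42	69	Sensory/somatomotor Mouth
32	-45	-32	47	Sensory/somatomotor Mouth
33	-21	-31	61	Sensory/somatomotor Mouth
34	-13	-17	75	Sensory/somatomotor Mouth
35	42	-20	55	Cingulo-opercular Task Control
36	-38	-15	69	Cingulo-opercular Task Control
37	-16	-46	73	Cingulo-opercular Task Control
38	2	-28	60	Cingulo-opercular Task Control
39	3	-17	58	Cingulo-opercular Task Control
40	38	-17	45	Cingulo-opercular Task Control
41	-49	-11	35	Cingulo-opercular Task Control
42	36	-9	14	Cingulo-opercular Task Control
43	51	-6	32	Cingulo-opercular Task Control
44	-53	-10	24	Cingulo-opercular Task Control
45	66	-8	25	Cingulo-opercular Task Control
46	-3	2	53	Cingulo-opercular Task Control
47	54	-28	34	Cingulo-opercular Task Control
48	19	-8	64	Cingulo-opercular Task Control
49	-16	-5	71	Auditory
50	-10	-2	42	Auditory
51	37	1	-4	Auditory
52	13	-1	70	Auditory
53	7	8	51	Auditory
54	-45	0	9	Auditory
55	49	8	-1	Auditory
56	-34	3	4	Auditory
57	-51	8	-2	Auditory
58	-5	18	34	Auditory
59	36	10	1	Auditory
60	32	-26	13	Auditory
61	65	-33	20	Auditory
62	58	-16	7	Default mode
63	-38	-33	17	Default mode
64	-60	-25	14	Default mode
65	-49	-26	5	Default mode
66	43	-23	20	Default mode
67	-50	-34	26	Default mode
68	-53	-22	23	Default mode
69	-55	-9	12	Default mode
70	56	-5	13	Default mode
71	59	-17	29	Default mode
72	-30	-27	12	Default mode
73	-41	-75	26	Default mode
74	6	67	-4	Default mode
75	8	48	-15	Default mode
76	-13	-40	1	Default mode
77	-18	63	-9	Default mode
78	-46	-61	21	Default mode
79	43	-72	28	Default mode
80	-44	12	-34	Default mode
81	46	16	-30	Default mode
82	-68	-23	-16	Default mode
83	-58	-26	-15	Default mode
84	27	16	-17	Default mode
85	-44	-65	35	Default mode
86	-39	-75	44	Default mode
87	-7	-55	27	Default mode
88	6	-59	35	Default mode
89	-11	-56	16	Default mode
90	-3	-49	13	Default mode
91	8	-48	31	Default mode
92	15	-63	26	Default mode
93	-2	-37	44	Default mode
94	11	-54	17	Default mode
95	52	-59	36	Default mode
96	23	33	48	Default mode
97	-10	39	52	Default mode
98	-16	29	53	Default mode
99	-35	20	51	Default mode
100	22	39	39	Default mode
101	13	55	38	Default mode
102	-10	55	39	Default mode
103	-20	45	39	Default mode
104	6	54	16	Default mode
105	6	64	22	Default mode
106	-7	51	-1	Default mode
107	9	54	3	Default mode
108	-3	44	-9	Default mode
109	8	42	-5	Default mode
110	-11	45	8	Default mode
111	-2	38	36	Default mode
112	-3	42	16	Default mode
113	-20	64	19	Default mode
114	-8	48	23	Default mode
115	65	-12	-19	Default mode
116	-56	-13	-10	Default mode
117	-58	-30	-4	Default mode
118	65	-31	-9	Default mode
119	-68	-41	-5	Default mode
120	13	30	59	Memory retrieval
121	12	36	20	Memory retrieval
122	52	-2	-16	Memory retrieval
123	-26	-40	-8	Memory retrieval
124	27	-37	-13	Memory retrieval
125	-34	-38	-16	Visual
126	28	-77	-32	Visual
127	52	7	-30	Visual
128	-53	3	-27	Visual
129	47	-50	29	Visual
130	-49	-42	1	Visual
131	-31	19	-19	Visual
132	-2	-35	31	Visual
133	-7	-71	42	Visual
134	11	-66	42	Visual
135	4	-48	51	Visual
136	-46	31	-13	Visual
137	-10	11	67	Visual
138	49	35	-12	Visual
139	8	-91	-7	Visual
140	17	-91	-14	Visual
141	-12	-95	-13	Visual
142	18	-47	-10	Visual
143	40	-72	14	Visual
144	8	-72	11	Visual
145	-8	-81	7	Visual
146	-28	-79	19	Visual
147	20	-66	2	Visual
148	-24	-91	19	Visual
149	27	-59	-9	Visual
150	-15	-72	-8	Visual
151	-18	-68	5	Visual
152	43	-78	-12	Visual
153	-47	-76	-10	Visual
154	-14	-91	31	Visual
155	15	-87	37	Visual
156	29	-77	25	Fronto-parietal Task Control
157	20	-86	-2	Fronto-parietal Task Control
158	15	-77	31	Fronto-parietal Task Control
159	-16	-52	-1	Fronto-parietal Task Control
160	42	-66	-8	Fronto-parietal Task Control
161	24	-87	24	Fronto-parietal Task Control
162	6	-72	24	Fronto-parietal Task Control
163	-42	-74	0	Fronto-parietal Task Control
164	26	-79	-16	Fronto-parietal Task Control
165	-16	-77	34	Fronto-parietal Task Control
166	-3	-81	21	Fronto-parietal Task Control
167	-40	-88	-6	Fronto-parietal Task Control
168	37	-84	13	Fronto-parietal Task Control
169	6	-81	6	Fronto-parietal Task Control
170	-26	-90	3	Fronto-parietal Task Control
171	-33	-79	-13	Fronto-parietal Task Control
172	37	-81	1	Fronto-parietal Task Control
173	-44	2	46	Fronto-parietal Task Control
174	48	25	27	Fronto-parietal Task Control
175	-47	11	23	Fronto-parietal Task Control
176	-53	-49	43	Fronto-parietal Task Control
177	-23	11	64	Fronto-parietal Task Control
178	58	-53	-14	Fronto-parietal Task Control
179	24	45	-15	Fronto-parietal Task Control
180	34	54	-13	Fronto-parietal Task Control
181	-21	41	-20	Salience
182	-18	-76	-24	Salience
183	17	-80	-34	Salience
184	35	-67	-34	Salience
185	47	10	33	Salience
186	-41	6	33	Salience
187	-42	38	21	Salience
188	38	43	15	Salience
189	49	-42	45	Salience
190	-28	-58	48	Salience
191	44	-53	47	Salience
192	32	14	56	Salience
193	37	-65	40	Salience
194	-42	-55	45	Salience
195	40	18	40	Salience
196	-34	55	4	Salience
197	-42	45	-2	Salience
198	33	-53	44	Salience
199	43	49	-2	Subcortical
200	-42	25	30	Subcortical
201	-3	26	44	Subcortical
202	11	-39	50	Subcortical
203	55	-45	37	Subcortical
204	42	0	47	Subcortical
205	31	33	26	Subcortical
206	48	22	10	Subcortical
207	-35	20	0	Subcortical
208	36	22	3	Subcortical
209	37	32	-2	Subcortical
210	34	16	-8	Subcortical
211	-11	26	25	Subcortical
212	-1	15	44	Ventral attention
213	-28	52	21	Ventral attention
214	0	30	27	Ventral attention
215	5	23	37	Ventral attention
216	10	22	27	Ventral attention
217	31	56	14	Ventral attention
218	26	50	27	Ventral attention
219	-39	51	17	Ventral attention
220	2	-24	30	Ventral attention
221	6	-24	0	Dorsal attention
222	-2	-13	12	Dorsal attention
223	-10	-18	7	Dorsal attention
224	12	-17	8	Dorsal attention
225	-5	-28	-4	Dorsal attention
226	-22	7	-5	Dorsal attention
227	-15	4	8	Dorsal attention
228	31	-14	2	Dorsal attention
229	23	10	1	Dorsal attention
230	29	1	4	Dorsal attention
231	-31	-11	0	Dorsal attention
232	15	5	7	unassigned
233	9	-4	6	unassigned
234	54	-43	22	unassigned
235	-56	-50	10	unassigned
236	-55	-40	14	unassigned
237	52	-33	8	unassigned
238	51	-29	-4	unassigned
239	56	-46	11	unassigned
240	53	33	1	unassigned
241	-49	25	-1	unassigned
242	-16	-65	-20	unassigned
243	-32	-55	-25	unassigned
244	22	-58	-23	unassigned
245	1	-62	-18	unassigned
246	33	-12	-34	unassigned
247	-31	-10	-36	unassigned
248	49	-3	-38	unassigned
249	-50	-7	-39	unassigned
250	10	-62	61	unassigned
251	-52	-63	5	unassigned
252	-47	-51	-21	unassigned
253	46	-47	-17	unassigned
254	47	-30	49	unassigned
255	22	-65	48	unassigned
256	46	-59	4	unassigned
257	25	-58	60	unassigned
258	-33	-46	47	unassigned
259	-27	-71	37	unassigned
260	-32	-1	54	unassigned
261	-42	-60	-9	unassigned
262	-17	-59	64	unassigned
263	29	-5	54	unassigned
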