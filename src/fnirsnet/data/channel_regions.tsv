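channel	region	hemisphere
1	right postcentral gyrus	right
2	right precentral gyrus	right
3	right middle frontal gyrus	right
4	right superior frontal gyrus	right
5	right medial superior frontal gyrus	right
6	left superior frontal gyrus	left
7	left middle frontal gyrus	left
8	left middle frontal gyrus	left
9	left postcentral gyrus	left
10	right supramarginal gyrus	right
11	right precentral gyrus	right
12	right triangular part of inferior frontal gyrus	right
13	right middle frontal gyrus	right
14	right superior frontal gyrus	right
15	left medial superior frontal gyrus	left
16	left middle frontal gyrus	left
17	left middle frontal gyrus	left
18	left precentral gyrus	left
19	left postcentral gyrus	left
20	right postcentral gyrus	right
21	right triangular part of inferior frontal gyrus	right
22	right middle frontal gyrus	right
23	right middle frontal gyrus	right
24	right medial superior frontal gyrus	right
25	left superior frontal gyrus	left
26	left middle frontal gyrus	left
27	left triangular part of inferior frontal gyrus	left
28	left postcentral gyrus	left
29	right superior temporal gyrus	right
30	right opercular part of inferior frontal gyrus	right
31	right triangular part of inferior frontal gyrus	right
32	right middle frontal gyrus	right
33	right superior frontal gyrus	right
34	left medial superior frontal gyrus	left
35	left middle frontal gyrus	left
36	left triangular part of inferior frontal gyrus	left
37	left triangular part of inferior frontal gyrus	left
38	left postcentral gyrus	left
39	right middle temporal gyrus	right
40	right triangular part of inferior frontal gyrus	right
41	right middle frontal gyrus	right
42	right superior frontal gyrus	right
43	right medial superior frontal gyrus	right
44	left superior frontal gyrus	left
45	left middle frontal gyrus	left
46	left triangular part of inferior frontal gyrus	left
47	left superior temporal gyrus	left
48	left supramarginal gyrus	left
49	left middle temporal gyrus	left
50	left middle occipital gyrus	left
51	left middle occipital gyrus	left
52	left calcarine sulcus	left
53	right superior occipital gyrus	right
54	right middle occipital gyrus	right
55	right middle temporal gyrus	right
56	right superior temporal gyrus	right
57	right supramarginal gyrus	right
58	left middle temporal gyrus	left
59	left middle occipital gyrus	left
60	left middle occipital gyrus	left
61	left middle occipital gyrus	left
62	left calcarine sulcus	left
63	right inferior occipital gyrus	right
64	right middle occipital gyrus	right
65	right middle temporal gyrus	right
66	right superior temporal gyrus	right
67	left middle temporal gyrus	left
68	left middle temporal gyrus	left
69	left inferior occipital gyrus	left
70	left lingual gyrus	left
71	left cerebellum crus II	left
72	right lingual gyrus	right
73	right inferior occipital gyrus	right
74	right inferior temporal gyrus	right
75	right middle temporal gyrus	right
76	left middle temporal gyrus	left
77	left middle temporal gyrus	left
78	left cerebellum crus I	left
79	left cerebellum crus I	left
80	left cerebellum crus II	left
81	right lingual gyrus	right
82	right cerebellum crus I	right
83	right cerebellum crus I	right
84	right inferior temporal gyrus	right
85	right middle temporal gyrus	right
86	left inferior temporal gyrus	left
87	left cerebellum crus I	left
88	left cerebellum crus II	left
89	left cerebellum crus III	left
90	left cerebellum crus IV	left
91	right cerebellum crus II	right
92	right cerebellum crus II	right
93	right cerebellum crus I	right
94	right inferior temporal gyrus	right
95	right superior frontal gyrus	right
96	right precentral gyrus	right
97	right superior parietal cortex	right
98	right superior parietal cortex	right
99	right superior frontal gyrus	right
100	right superior frontal gyrus	right
101	right precentral gyrus	right
102	right superior parietal cortex	right
103	right cuneus	right
104	supplementary motor area	midline
105	left paracentral lobule	left
106	left precuneus	left
107	left precuneus	left
108	left superior frontal gyrus	left
109	left superior frontal gyrus	left
110	left paracentral lobule	left
111	left superior parietal cortex	left
112	left superior parietal cortex	left
113	left superior frontal gyrus	left
114	left precentral gyrus	left
115	left postcentral gyrus	left
116	left superior parietal cortex	left
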